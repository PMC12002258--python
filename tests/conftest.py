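import io

import pandas as pd
import pytest

import paleosar as ps


def occurrence_csv(rows, columns=None):
    """Build an in-memory PBDB-dialect CSV from row dicts."""
    cols = columns or ["accepted_name", "accepted_rank", "collection_no",
                       "paleolng", "paleolat", "early_interval", "late_interval",
                       "class", "order"]
    df = pd.DataFrame(rows, columns=cols)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf


def pbdb_row(name="Tyrannosaurus rex", rank="species", coll=1, lon=-100.0,
             lat=45.0, early="Maastrichtian", late="", cls="Reptilia",
             order="Saurischia"):
    return {"accepted_name": name, "accepted_rank": rank, "collection_no": coll,
            "paleolng": lon, "paleolat": lat, "early_interval": early,
            "late_interval": late, "class": cls, "order": order}


@pytest.fixture
def loaded_community():
    """Default synthetic community, loaded and binned (shared, read-only)."""
    table, truth = ps.generate_power_law_community(seed=0)
    buf = io.StringIO()
    table.to_csv(buf, index=False)
    buf.seek(0)
    occ, _ = ps.load_occurrences(buf)
    occ, _ = ps.assign_time_bins(occ, ps.TimeBinScheme.single_bin())
    return occ, truth


def random_points(rng, n, lon_span=30.0, lat_span=20.0):
    return pd.DataFrame({
        "cell_id": [f"p{i}" for i in range(n)],
        "lon": rng.uniform(-lon_span, lon_span, n),
        "lat": rng.uniform(-lat_span, lat_span, n),
    })
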