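"""Loading, group filtering and time binning of occurrence tables."""
import warnings

import pytest

import paleosar as ps
from paleosar.occurrences import DEFAULT_GROUPS

from conftest import occurrence_csv, pbdb_row


class TestLoad:
    def test_empty_csv_with_headers_gives_empty_table(self):
        table, report = ps.load_occurrences(occurrence_csv([]))
        assert len(table) == 0
        assert report.n_input == 0 and report.n_kept == 0 and report.n_dropped == 0

    def test_row_missing_coordinate_dropped_and_reported(self):
        rows = [pbdb_row(coll=i) for i in range(1, 6)]
        rows[2]["paleolat"] = None
        table, report = ps.load_occurrences(occurrence_csv(rows))
        assert len(table) == 4
        assert report.dropped == {"missing coordinate": 1}
        assert report.n_kept + report.n_dropped == report.n_input == 5

    def test_genus_level_records_dropped(self):
        rows = [pbdb_row(), pbdb_row(name="Tyrannosaurus", rank="genus", coll=2)]
        table, report = ps.load_occurrences(occurrence_csv(rows))
        assert len(table) == 1
        assert report.dropped == {"not species level": 1}

    def test_species_name_normalized(self):
        rows = [pbdb_row(name="  Homo   sapiens ")]
        table, _ = ps.load_occurrences(occurrence_csv(rows))
        assert table["species"].iloc[0] == "Homo sapiens"

    def test_missing_required_column_names_it(self):
        buf = occurrence_csv([pbdb_row()],
                             columns=["accepted_name", "collection_no", "paleolng",
                                      "early_interval", "late_interval"])
        with pytest.raises(ps.ConfigurationError, match="paleolat"):
            ps.load_occurrences(buf)

    def test_entirely_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ps.ConfigurationError, match="empty"):
            ps.load_occurrences(path)

    def test_user_exclusion_list(self):
        rows = [pbdb_row(), pbdb_row(name="Edmontosaurus annectens", coll=2)]
        table, report = ps.load_occurrences(
            occurrence_csv(rows), exclude_species=["Edmontosaurus  annectens"])
        assert len(table) == 1
        assert report.dropped == {"user exclusion": 1}


def _mixed_fauna_rows():
    dinos = [pbdb_row(name=f"Dino sp{i}", coll=i, cls="Dinosauria", order="Ornithischia")
             for i in range(1, 4)]
    birds = [pbdb_row(name=f"Avis sp{i}", coll=10 + i, cls="Dinosauria", order="Aves")
             for i in range(1, 3)]
    mammals = [pbdb_row(name="Mus primus", coll=20, cls="Mammaliamorpha", order="Rodentia")]
    return dinos + birds + mammals


class TestFilterGroup:
    def test_dinosauria_excluding_aves(self):
        table, _ = ps.load_occurrences(occurrence_csv(_mixed_fauna_rows()))
        rule = ps.GroupRule("dinosaurs", "Dinosauria", ("Aves",))
        out = ps.filter_group(table, rule)
        assert len(out) == 3
        assert all("Dino" in s for s in out["species"])

    def test_identity_when_include_everywhere_and_no_excludes(self):
        table, _ = ps.load_occurrences(occurrence_csv(_mixed_fauna_rows()))
        rule = ps.GroupRule("dinos", "Dinosauria")
        out = ps.filter_group(table, rule)
        assert len(out) == 5  # all Dinosauria rows, birds included
        again = ps.filter_group(out, rule)
        assert again.equals(out)  # idempotent

    def test_mammaliamorpha_excluding_chiroptera_drops_bats(self):
        rows = [pbdb_row(name="Mus primus", cls="Mammaliamorpha", order="Rodentia"),
                pbdb_row(name="Vesper bat", coll=2, cls="Mammaliamorpha",
                         order="Chiroptera")]
        table, _ = ps.load_occurrences(occurrence_csv(rows))
        out = ps.filter_group(table, DEFAULT_GROUPS["mammals"])
        assert list(out["species"]) == ["Mus primus"]

    def test_absent_clade_warns_and_returns_empty(self):
        table, _ = ps.load_occurrences(occurrence_csv(_mixed_fauna_rows()))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out = ps.filter_group(table, ps.GroupRule("x", "Trilobita"))
        assert len(out) == 0
        assert any("Trilobita" in str(w.message) for w in caught)


class TestTimeBins:
    def test_same_interval_direct_lookup(self):
        table, _ = ps.load_occurrences(occurrence_csv(
            [pbdb_row(early="Maastrichtian", late="Maastrichtian")]))
        out, report = ps.assign_time_bins(table, ps.TimeBinScheme.stage_composite())
        assert list(out["bin"]) == ["Maastrichtian"]
        assert report.n_dropped == 0

    def test_bin_spanning_record_dropped(self):
        table, _ = ps.load_occurrences(occurrence_csv(
            [pbdb_row(early="Campanian", late="Maastrichtian")]))
        out, report = ps.assign_time_bins(table, ps.TimeBinScheme.stage_composite())
        assert len(out) == 0
        assert report.dropped == {"spanning bins": 1}

    def test_nalma_scheme_puercan(self):
        table, _ = ps.load_occurrences(occurrence_csv(
            [pbdb_row(early="Puercan", late="Puercan")]))
        out, _ = ps.assign_time_bins(table, ps.TimeBinScheme.substage_nalma())
        assert list(out["bin"]) == ["Puercan"]

    def test_unknown_interval_tallied_not_fatal(self):
        table, _ = ps.load_occurrences(occurrence_csv(
            [pbdb_row(early="Jurassic Park", late="")]))
        out, report = ps.assign_time_bins(table, ps.TimeBinScheme.stage_composite())
        assert len(out) == 0
        assert report.dropped == {"unresolvable interval": 1}

    def test_blank_late_interval_inherits_early(self):
        table, _ = ps.load_occurrences(occurrence_csv(
            [pbdb_row(early="Danian", late="")]))
        out, _ = ps.assign_time_bins(table, ps.TimeBinScheme.stage_composite())
        assert list(out["bin"]) == ["Danian"]

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ps.ConfigurationError):
            ps.TimeBinScheme(bins=(("A", ("Danian",)), ("B", ("Danian",))))

    def test_filter_and_bin_commute(self):
        rows = _mixed_fauna_rows()
        rows[0]["early_interval"] = "Campanian"
        table, _ = ps.load_occurrences(occurrence_csv(rows))
        scheme = ps.TimeBinScheme.stage_composite()
        rule = DEFAULT_GROUPS["dinosaurs"]
        a = ps.assign_time_bins(ps.filter_group(table, rule), scheme)[0]
        b = ps.filter_group(ps.assign_time_bins(table, scheme)[0], rule)
        assert a.reset_index(drop=True).equals(b.reset_index(drop=True))

    def test_counts_conserved_across_stages(self):
        rows = _mixed_fauna_rows()
        rows[1]["paleolng"] = None
        rows[4]["early_interval"] = "Atlantis"
        table, load_rep = ps.load_occurrences(occurrence_csv(rows))
        assert load_rep.n_kept + load_rep.n_dropped == load_rep.n_input
        out, bin_rep = ps.assign_time_bins(table, ps.TimeBinScheme.stage_composite())
        assert bin_rep.n_kept + bin_rep.n_dropped == len(table)
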