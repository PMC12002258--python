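"""Synthetic fossil-occurrence generators with known spatial structure.

`generate_power_law_community` builds a flat landscape (embedded on the
equator so great-circle and planar distances agree to first order) in which
species have disc-shaped geographic ranges with centres placed uniformly at
random and a skewed species-abundance distribution.  Because ranges are
spatially aggregated, nested SARs over this landscape follow an approximate
power law whose parameters are fixed by the community geometry -- the truth
record returned alongside the table carries the complete (fully censused)
species pool of every occupied grid cell, so the true SAR is computable for
any set of regions.  Collections are placed in clusters (fossil localities
are not uniform either) and sample only species present in their grid cell,
weighted by abundance.

Ranges are rasterized to the analysis grid (a species is present in a cell
iff its range disc reaches the cell midpoint) so the occurrence table and
the truth record agree exactly by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import KM_PER_DEG, EqualAreaGrid

__all__ = ["CommunityParams", "generate_power_law_community",
           "true_sar_for_regions", "generate_occurrence_table_from_senm"]


@dataclass(frozen=True)
class CommunityParams:
    """Knobs of the disc-range community generator.

    Defaults emulate one well-sampled continental time bin of a vertebrate
    fossil record: a 3000 x 1200 km landscape, 250 species with lognormal
    abundances, range radii lognormal around ~450 km, and 700 collections
    averaging ~4 occurrences each (the occurrence-per-collection intensity
    typical of vertebrate occurrence databases), gathered into 8 spatial
    clusters so that occupied grid cells hold on the order of ten
    collections apiece.
    """

    n_species: int = 250
    domain_km: tuple = (3000.0, 1200.0)
    range_radius_km: tuple = ("lognormal", 6.1, 0.5)   # median ~ e^6.1 = 446 km
    sad: tuple = ("lognormal", 0.0, 1.2)
    n_collections: int = 700
    occ_per_collection: tuple = ("poisson", 4.0)
    n_clusters: int = 8
    cluster_sd_km: float = 60.0
    grid_spacing_km: float = 100.0
    bin_name: str = "Synthetic"
    retry_cap: int = 200

    def __post_init__(self):
        if min(self.n_species, self.n_collections, self.n_clusters) < 1:
            raise ValueError("counts must be positive")
        if self.sad[0] not in ("lognormal", "logseries"):
            raise ValueError(f"unknown SAD {self.sad[0]!r}")
        if self.range_radius_km[0] not in ("lognormal", "fixed"):
            raise ValueError(f"unknown radius spec {self.range_radius_km[0]!r}")
        if self.occ_per_collection[0] not in ("poisson", "fixed"):
            raise ValueError(f"unknown occurrence spec {self.occ_per_collection[0]!r}")


def _draw_sad(params: CommunityParams, rng) -> np.ndarray:
    kind = params.sad[0]
    if kind == "lognormal":
        _, mu, sigma = params.sad
        w = rng.lognormal(mu, sigma, params.n_species)
    else:                                   # logseries via its standard pmf
        _, alpha = params.sad
        from scipy.stats import logser
        w = logser.rvs(alpha, size=params.n_species, random_state=rng).astype(float)
    return w / w.sum()


def _draw_radii(params: CommunityParams, rng) -> np.ndarray:
    kind = params.range_radius_km[0]
    if kind == "fixed":
        return np.full(params.n_species, float(params.range_radius_km[1]))
    _, mu, sigma = params.range_radius_km
    return rng.lognormal(mu, sigma, params.n_species)


def _embed(x_km, y_km, domain):
    """Centre the planar landscape on (0 degrees, 0 degrees)."""
    w, h = domain
    lon = (np.asarray(x_km) - w / 2.0) / KM_PER_DEG
    lat = (np.asarray(y_km) - h / 2.0) / KM_PER_DEG
    return lon, lat


def generate_power_law_community(params: CommunityParams = None, seed: int = 0):
    """Generate an occurrence table plus its truth record.

    Returns
    -------
    table : DataFrame
        PBDB-dialect occurrence CSV columns (``accepted_name``,
        ``accepted_rank``, ``collection_no``, ``paleolng``, ``paleolat``,
        ``early_interval``, ``late_interval``, ``class``).
    truth : dict
        ``cells``: {cell_id: sorted species indices present},
        ``rel_abundance``: global relative abundance per species,
        ``seed``/``params`` for provenance.
    """
    params = params or CommunityParams()
    rng = np.random.default_rng(seed)
    w, h = params.domain_km

    centers = np.column_stack([rng.uniform(0, w, params.n_species),
                               rng.uniform(0, h, params.n_species)])
    radii = _draw_radii(params, rng)
    p = _draw_sad(params, rng)

    grid = EqualAreaGrid(params.grid_spacing_km)

    cluster_centers = np.column_stack([rng.uniform(0, w, params.n_clusters),
                                       rng.uniform(0, h, params.n_clusters)])

    def cell_presence(cell_id):
        lon, lat = grid.midpoint(cell_id)
        mx = lon * KM_PER_DEG + w / 2.0
        my = lat * KM_PER_DEG + h / 2.0
        d = np.hypot(centers[:, 0] - mx, centers[:, 1] - my)
        return np.flatnonzero(d <= radii)

    presence_cache: dict = {}
    rows = []
    n_occ_kind, n_occ_param = params.occ_per_collection
    for coll in range(params.n_collections):
        for _ in range(params.retry_cap):
            c = cluster_centers[rng.integers(params.n_clusters)]
            pos = c + rng.normal(0.0, params.cluster_sd_km, 2)
            if not (0 <= pos[0] < w and 0 <= pos[1] < h):
                continue
            lon, lat = _embed(pos[0], pos[1], params.domain_km)
            cid = grid.cell_of(float(lon), float(lat))
            if cid not in presence_cache:
                presence_cache[cid] = cell_presence(cid)
            pool = presence_cache[cid]
            if len(pool):
                break
        else:
            raise RuntimeError("could not place a collection on any occupied range; "
                               "ranges too small for this landscape")
        if n_occ_kind == "poisson":
            n_occ = max(1, int(rng.poisson(n_occ_param)))
        else:
            n_occ = int(n_occ_param)
        weights = p[pool] / p[pool].sum()
        draws = rng.choice(pool, size=n_occ, p=weights)
        for s in draws:
            rows.append({
                "accepted_name": f"Synthetica sp{int(s):04d}",
                "accepted_rank": "species",
                "collection_no": coll + 1,
                "paleolng": float(lon), "paleolat": float(lat),
                "early_interval": params.bin_name,
                "late_interval": params.bin_name,
                "class": "Synthetica",
            })
    table = pd.DataFrame(rows)

    occupied = sorted(presence_cache)
    truth = {
        "cells": {cid: sorted(int(s) for s in presence_cache[cid]) for cid in occupied},
        "rel_abundance": p.tolist(),
        "grid_spacing_km": params.grid_spacing_km,
        "seed": int(seed),
        "params": {"n_species": params.n_species, "domain_km": list(params.domain_km),
                   "n_collections": params.n_collections},
    }
    return table, truth


def true_sar_for_regions(truth: dict, region_cells, quorum=None):
    """True richness for each region (an iterable of cell-id sets).

    With ``quorum=None`` returns the face-value census richness (number of
    species present in any member cell).  With a quorum, returns the
    coverage-standardized richness of the region's true abundance vector,
    where a species' regional weight is its global relative abundance times
    the number of member cells it occupies.
    """
    from .diversity import true_richness_at_coverage

    p = np.asarray(truth["rel_abundance"], dtype=float)
    cells = truth["cells"]
    out = []
    for cellset in region_cells:
        counts: dict = {}
        for cid in cellset:
            for s in cells.get(cid, ()):
                counts[s] = counts.get(s, 0) + 1
        if not counts:
            out.append(np.nan)
            continue
        if quorum is None:
            out.append(float(len(counts)))
        else:
            sp = np.array(sorted(counts))
            weights = p[sp] * np.array([counts[s] for s in sp], dtype=float)
            out.append(true_richness_at_coverage(weights, quorum))
    return np.asarray(out)


def generate_occurrence_table_from_senm(params, template_spec: dict = None,
                                        seed: int = 0) -> pd.DataFrame:
    """Neutral-model occurrence table: simulate + fossilize in one call.

    ``template_spec`` keys (all optional): ``n_cells`` (default 24, chosen as
    a random subset of the landscape), ``collections_per_cell`` (default 3),
    ``occ_per_collection`` (default 10).
    """
    from .senm import fossilize, simulate_neutral_sample

    spec = {"n_cells": 24, "collections_per_cell": 3, "occ_per_collection": 10}
    if template_spec:
        spec.update(template_spec)
    rng = np.random.default_rng(seed)
    nx, ny, _ = params.landscape
    all_cells = [(ix, iy) for ix in range(nx) for iy in range(ny)]
    pick = rng.choice(len(all_cells), size=min(spec["n_cells"], len(all_cells)),
                      replace=False)
    cells = [all_cells[i] for i in sorted(pick)]
    rows, coll = [], 1
    for ix, iy in cells:
        for _ in range(spec["collections_per_cell"]):
            rows.append({"cell_x": ix, "cell_y": iy, "collection": coll,
                         "n_occ": spec["occ_per_collection"]})
            coll += 1
    template = pd.DataFrame(rows)
    assemblage = simulate_neutral_sample(params, cells, params.density,
                                         seed=int(rng.integers(2**31)))
    return fossilize(assemblage, template, seed=int(rng.integers(2**31)))
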