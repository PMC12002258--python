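"""Spatially explicit neutral model (SENM): coalescence sampler, forward
oracle, and fossil-structure subsampling experiments.

The model is a zero-sum neutral community on a rectangular lattice of cells,
each holding a fixed number (``density``) of demographically equivalent
individuals.  Each generation every individual is replaced by the offspring
of a parent: with probability ``nu`` the offspring founds a new species
(point speciation); otherwise the parent's cell is drawn from the child's
cell through a dispersal kernel (child-centred formulation) and the parent
is a uniform individual of that cell.

Species identities of a *sample* are generated backward in time by the exact
coalescent dual of that process: every sampled individual starts a lineage;
per generation each lineage speciates with probability ``nu`` or jumps to a
parent (cell via the kernel, slot uniform), and lineages landing on the same
parent coalesce.  Termination is guaranteed for ``nu > 0``.  Backward
simulation touches only the sampled lineages, which is what makes
continent-scale assemblages cheap.  A brute-force forward-time simulator
(`forward_oracle`) is provided solely to validate the sampler on tiny
lattices; in the well-mixed limit (``kernel="global"``) the sampler's mean
species count follows the Ewens sampling formula with
``theta = 2 * J * nu``.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NeutralParams", "SimulatedAssemblage", "simulate_neutral_sample",
           "forward_oracle", "fossilize", "senm_experiment",
           "ewens_expected_richness"]

_FORWARD_MAX_CELLS = 225      # forward oracle refuses anything above 15 x 15


@dataclass(frozen=True)
class NeutralParams:
    """Parameters of the spatial neutral community.

    nu : per-birth speciation probability in (0, 1].
    dispersal_sigma : kernel scale in km.
    landscape : (width_cells, height_cells, cell_pitch_km).
    density : individuals per cell.
    kernel : "gaussian" (default), "fat_tailed" (t with 3 df per axis), or
        "global" (uniform over the landscape; the well-mixed limit).
    """

    nu: float
    dispersal_sigma: float = 100.0
    landscape: tuple = (20, 20, 100.0)
    density: int = 50
    kernel: str = "gaussian"

    def __post_init__(self):
        if not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must lie in (0, 1]; nu=0 never terminates")
        if self.dispersal_sigma <= 0:
            raise ValueError("dispersal_sigma must be positive")
        if self.density < 1:
            raise ValueError("density must be >= 1")
        if self.kernel not in ("gaussian", "fat_tailed", "global"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def n_cells(self) -> int:
        return self.landscape[0] * self.landscape[1]

    @property
    def j_total(self) -> int:
        return self.n_cells * self.density


@dataclass
class SimulatedAssemblage:
    """Sampled species counts per cell: ``{(ix, iy): Counter(species: n)}``."""

    cells: dict
    params: NeutralParams
    seed: int = 0

    def richness(self) -> int:
        sp = set()
        for c in self.cells.values():
            sp.update(c)
        return len(sp)

    def abundance(self) -> Counter:
        tot = Counter()
        for c in self.cells.values():
            tot.update(c)
        return tot


def ewens_expected_richness(theta: float, n: int) -> float:
    """Ewens sampling formula expectation: ``sum_{i=0}^{n-1} theta/(theta+i)``."""
    i = np.arange(n)
    return float(np.sum(theta / (theta + i)))


def _disperse(params: NeutralParams, x, y, rng):
    """Parent cells for lineages/children at cells (x, y), child-centred."""
    nx, ny, pitch = params.landscape
    k = len(x)
    if params.kernel == "global":
        return rng.integers(0, nx, k), rng.integers(0, ny, k)
    if params.kernel == "gaussian":
        dx = rng.normal(0.0, params.dispersal_sigma, k)
        dy = rng.normal(0.0, params.dispersal_sigma, k)
    else:                                   # fat-tailed: t(3) per axis
        dx = rng.standard_t(3, k) * params.dispersal_sigma
        dy = rng.standard_t(3, k) * params.dispersal_sigma
    px = (x + 0.5) * pitch + dx
    py = (y + 0.5) * pitch + dy
    px = _reflect(px, nx * pitch)
    py = _reflect(py, ny * pitch)
    return (np.minimum((px / pitch).astype(int), nx - 1),
            np.minimum((py / pitch).astype(int), ny - 1))


def _reflect(pos, length):
    # fold a continuous coordinate into [0, length) with reflecting edges
    period = 2.0 * length
    p = np.mod(pos, period)
    return np.where(p >= length, period - p - 1e-12, p)


def simulate_neutral_sample(params: NeutralParams, sample_cells, n_per_cell,
                            seed: int = 0) -> SimulatedAssemblage:
    """Species identities of a spatial sample under the neutral model.

    Parameters
    ----------
    params : NeutralParams
    sample_cells : sequence of (ix, iy)
        Lattice cells to sample; must lie inside the landscape.
    n_per_cell : int or sequence of int
        Individuals sampled per cell (at most ``density``).
    seed : int

    Returns
    -------
    SimulatedAssemblage
    """
    nx, ny, _ = params.landscape
    cells = [tuple(c) for c in sample_cells]
    if np.isscalar(n_per_cell):
        n_per_cell = [int(n_per_cell)] * len(cells)
    for (ix, iy), npc in zip(cells, n_per_cell):
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise ValueError(f"sample cell {(ix, iy)} outside landscape {nx}x{ny}")
        if npc > params.density:
            raise ValueError("cannot sample more individuals than a cell holds")

    rng = np.random.default_rng(seed)
    xs, ys, owner = [], [], []
    for c_idx, ((ix, iy), npc) in enumerate(zip(cells, n_per_cell)):
        xs.extend([ix] * npc)
        ys.extend([iy] * npc)
        owner.extend([c_idx] * npc)
    n_samp = len(xs)
    species = np.full(n_samp, -1, dtype=np.int64)
    next_sp = 0

    x = np.array(xs, dtype=np.int64)
    y = np.array(ys, dtype=np.int64)
    # sampled individuals are distinct, so lineages start unmerged even when
    # they share a cell; merging can only happen after a parent draw
    members = [np.array([i]) for i in range(n_samp)]

    while len(members):
        k = len(members)
        if k == 1:
            # the last lineage's ancestor must eventually speciate
            species[members[0]] = next_sp
            next_sp += 1
            break
        if k == 2 and params.kernel == "global":
            # exact competing-geometric shortcut for the final pair
            s = 1.0 - (1.0 - params.nu) ** 2
            c = (1.0 - params.nu) ** 2 / params.j_total
            if rng.random() < s / (s + c):
                species[members[0]] = next_sp
                species[members[1]] = next_sp + 1
                next_sp += 2
            else:
                species[members[0]] = next_sp
                species[members[1]] = next_sp
                next_sp += 1
            break
        speciate = rng.random(k) < params.nu
        if speciate.any():
            for i in np.flatnonzero(speciate):
                species[members[i]] = next_sp
                next_sp += 1
            keep = ~speciate
            members = [m for m, kp in zip(members, keep) if kp]
            x, y = x[keep], y[keep]
            if not len(members):
                break
        px, py = _disperse(params, x, y, rng)
        slots = rng.integers(0, params.density, len(members))
        key = (px * ny + py) * params.density + slots
        order = np.argsort(key, kind="stable")
        new_members, new_x, new_y = [], [], []
        i = 0
        while i < len(order):
            j = i + 1
            while j < len(order) and key[order[j]] == key[order[i]]:
                j += 1
            grp = order[i:j]
            if len(grp) == 1:
                new_members.append(members[grp[0]])
            else:
                new_members.append(np.concatenate([members[g] for g in grp]))
            new_x.append(px[grp[0]])
            new_y.append(py[grp[0]])
            i = j
        members = new_members
        x = np.array(new_x, dtype=np.int64)
        y = np.array(new_y, dtype=np.int64)

    out: dict = {c: Counter() for c in cells}
    owner = np.array(owner)
    for c_idx, c in enumerate(cells):
        mine = species[owner == c_idx]
        out[c] = Counter(int(s) for s in mine)
    return SimulatedAssemblage(cells=out, params=params, seed=seed)


def forward_oracle(params: NeutralParams, generations: int, seed: int = 0):
    """Explicit forward-time zero-sum neutral dynamics on a tiny lattice.

    Runs the full community (every individual) for ``generations`` steps from
    an all-distinct start and returns a callable that samples assemblages
    from the final state.  Exists purely as a distributional oracle for
    :func:`simulate_neutral_sample`; refuses lattices above 15 x 15.
    """
    nx, ny, _ = params.landscape
    if nx * ny > _FORWARD_MAX_CELLS:
        raise ValueError(
            f"forward oracle is desk-scale only (<= {_FORWARD_MAX_CELLS} cells)")
    rng = np.random.default_rng(seed)
    dens = params.density
    n_tot = nx * ny * dens
    cell_x = np.repeat(np.arange(nx), ny * dens)
    cell_y = np.tile(np.repeat(np.arange(ny), dens), nx)
    species = np.arange(n_tot, dtype=np.int64)
    next_sp = n_tot
    for _ in range(generations):
        px, py = _disperse(params, cell_x, cell_y, rng)
        pidx = (px * ny + py) * dens + rng.integers(0, dens, n_tot)
        new = species[pidx]
        mut = rng.random(n_tot) < params.nu
        n_mut = int(mut.sum())
        if n_mut:
            new[mut] = np.arange(next_sp, next_sp + n_mut)
            next_sp += n_mut
        species = new

    state = species.reshape(nx, ny, dens)

    def sample(sample_cells, n_per_cell, sample_seed=0) -> SimulatedAssemblage:
        srng = np.random.default_rng(sample_seed)
        if np.isscalar(n_per_cell):
            n_per_cell = [int(n_per_cell)] * len(sample_cells)
        out = {}
        for (ix, iy), npc in zip(sample_cells, n_per_cell):
            picks = srng.choice(dens, size=npc, replace=False)
            out[(ix, iy)] = Counter(int(s) for s in state[ix, iy, picks])
        return SimulatedAssemblage(cells=out, params=params, seed=seed)

    return sample


def fossilize(assemblage: SimulatedAssemblage, template: pd.DataFrame,
              seed: int = 0, taxon_prefix: str = "Neutralus") -> pd.DataFrame:
    """Subsample an assemblage with the spatial structure of a fossil record.

    ``template`` has one row per collection with columns ``cell_x``,
    ``cell_y``, ``collection`` and ``n_occ``; occurrences are drawn (with
    replacement) from the assemblage's per-cell species abundances so the
    output carries exactly the template's per-cell occurrence counts.

    Returns an occurrence table in the PBDB flat-CSV dialect, with lattice
    cells embedded on the equator (cell pitch converted to degrees) so the
    table feeds directly into the gridding pipeline.
    """
    from .grid import KM_PER_DEG

    nx, ny, pitch = assemblage.params.landscape
    rng = np.random.default_rng(seed)
    rows = []
    for rec in template.itertuples(index=False):
        cell = (int(rec.cell_x), int(rec.cell_y))
        if not (0 <= cell[0] < nx and 0 <= cell[1] < ny):
            raise ValueError(f"template cell {cell} outside landscape {nx}x{ny}")
        pool = assemblage.cells.get(cell)
        if not pool:
            raise ValueError(f"assemblage has no individuals in template cell {cell}")
        sp = np.array(sorted(pool))
        w = np.array([pool[s] for s in sp], dtype=float)
        draws = rng.choice(sp, size=int(rec.n_occ), p=w / w.sum())
        lon = ((cell[0] + 0.5) * pitch - nx * pitch / 2.0) / KM_PER_DEG
        lat = ((cell[1] + 0.5) * pitch - ny * pitch / 2.0) / KM_PER_DEG
        for s in draws:
            rows.append({
                "accepted_name": f"{taxon_prefix} sp{int(s)}",
                "accepted_rank": "species",
                "collection_no": int(rec.collection),
                "paleolng": lon, "paleolat": lat,
                "early_interval": "Synthetic", "late_interval": "Synthetic",
                "class": taxon_prefix,
            })
    return pd.DataFrame(rows)


def _true_sar_points(assemblage: SimulatedAssemblage, quorum=None,
                     cutoff_km: float = 1e9, min_nodes: int = 2,
                     max_nn_km: float = 1e9):
    """True SAR points (region MST length, census richness) for the sampled
    cells, using the same nested-region machinery as the empirical pipeline.
    With a quorum, richness is the coverage-standardized richness of the
    region's true abundance distribution (the census counts are the complete
    community, so the infinite-community coverage formula applies, not the
    finite-sample estimator)."""
    from .diversity import true_richness_at_coverage
    from .grid import KM_PER_DEG
    from .regions import build_mst, enumerate_nested_regions, screen_regions, split_subtrees

    nx, ny, pitch = assemblage.params.landscape
    cells = sorted(assemblage.cells)
    pts = pd.DataFrame({
        "cell_id": [f"{ix}_{iy}" for ix, iy in cells],
        "lon": [((ix + 0.5) * pitch - nx * pitch / 2.0) / KM_PER_DEG for ix, iy in cells],
        "lat": [((iy + 0.5) * pitch - ny * pitch / 2.0) / KM_PER_DEG for ix, iy in cells],
    })
    counters = {f"{ix}_{iy}": assemblage.cells[(ix, iy)] for ix, iy in cells}
    mst = build_mst(pts)
    subtrees, _ = split_subtrees(mst, cutoff_km=cutoff_km, min_nodes=min_nodes)
    rows = []
    for st in subtrees:
        regions = enumerate_nested_regions(st, seed=0)
        regions, _ = screen_regions(regions, max_nn_km=max_nn_km)
        for r in regions:
            pooled = Counter()
            for cid in r.cells:
                pooled.update(counters[cid])
            if quorum is None:
                rich = float(len(pooled))
            else:
                rich = true_richness_at_coverage(
                    np.array(list(pooled.values()), dtype=float), quorum)
            rows.append({"mst_km": r.mst_km, "richness": rich})
    return pd.DataFrame(rows)


def senm_experiment(param_sets, template: pd.DataFrame, n_reps: int = 10,
                    seed: int = 0, quorum: float = 0.8,
                    cutoff_km: float = 1000.0, min_nodes: int = 4,
                    max_nn_km: float = 1000.0, min_region_n: int = 10,
                    true_quorum: bool = True, true_cutoff_km: float = 1000.0,
                    true_max_nn_km: float = 1000.0) -> pd.DataFrame:
    """Validation experiment: true vs pipeline-estimated SARs.

    For every parameter set and replicate: simulate a complete census of the
    template's cells, compute the TRUE SAR from the census, fossilize the
    assemblage to the template's sampling structure, run the empirical
    pipeline (grid -> regions -> SQS and face-value richness -> OLS), and
    record true and estimated slope and 100 km intercept.

    ``true_quorum=True`` standardizes the truth to the same coverage quorum
    as the estimate, isolating estimator fidelity from the (known, downward)
    offset between census richness and coverage-standardized richness.
    The truth SAR is screened with ``true_cutoff_km``/``true_max_nn_km``
    (long branches excluded by default) independently of the estimate's
    ``cutoff_km``/``max_nn_km``, so the cost of *including* long branches in
    the estimate can be measured against a fixed baseline.
    """
    from .pipeline import build_sar_table
    from .sar import SpeciesAreaModel

    ss = np.random.SeedSequence(seed)
    rows = []
    for p_idx, params in enumerate(param_sets):
        cells = sorted({(int(r.cell_x), int(r.cell_y))
                        for r in template.itertuples(index=False)})
        for rep in range(n_reps):
            s_sim, s_foss, s_pipe = [int(s.generate_state(1)[0] % (2**31))
                                     for s in ss.spawn(3)]
            census = simulate_neutral_sample(params, cells, params.density, seed=s_sim)
            true_pts = _true_sar_points(census, quorum=quorum if true_quorum else None,
                                        cutoff_km=true_cutoff_km, min_nodes=min_nodes,
                                        max_nn_km=true_max_nn_km)
            occ = fossilize(census, template, seed=s_foss)
            occ = occ.rename(columns={
                "accepted_name": "species", "collection_no": "collection",
                "paleolng": "lon", "paleolat": "lat"})
            occ["bin"] = "Synthetic"
            occ["group"] = "all"
            est = build_sar_table(occ, spacing_km=min(max(params.landscape[2], 25), 500),
                                  cutoff_km=cutoff_km, min_nodes=min_nodes,
                                  max_nn_km=max_nn_km, quorum=quorum,
                                  min_region_n=min_region_n, seed=s_pipe)
            row = {"param_set": p_idx, "rep": rep, "nu": params.nu,
                   "dispersal_sigma": params.dispersal_sigma,
                   "n_regions_est": len(est)}
            try:
                tfit = SpeciesAreaModel(true_pts["mst_km"], true_pts["richness"]).fit()
                row["true_slope"] = tfit.slope_z
                row["true_c100"] = tfit.intercept_c100
            except ValueError:
                row["true_slope"] = np.nan
                row["true_c100"] = np.nan
            for metric in ("sqs", "face"):
                col = "richness_sqs" if metric == "sqs" else "richness_face"
                usable = est[est["usable"]] if metric == "sqs" else est
                try:
                    fit = SpeciesAreaModel(usable["mst_km"], usable[col]).fit()
                    row[f"est_slope_{metric}"] = fit.slope_z
                    row[f"est_c100_{metric}"] = fit.intercept_c100
                except (ValueError, KeyError):
                    row[f"est_slope_{metric}"] = np.nan
                    row[f"est_c100_{metric}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
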