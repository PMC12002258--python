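"""Minimum-spanning-tree spatial subsampling: contiguous subtrees and
nested-region enumeration.

The spatial "area" axis used throughout is the summed MST length in km of a
set of grid-cell midpoints.  Nested regions are grown by single-linkage
accretion: starting from every cell in turn, the point nearest to the current
set (minimum great-circle distance to any member) is added one at a time, and
each intermediate set is emitted as a candidate region.  That accretion order
is exactly Prim's algorithm, so the running sum of accretion distances equals
the MST length of each intermediate region, computed on the region's own
cells.  Duplicate regions (identical unordered cell sets reached from
different starting points) are removed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst

from .grid import pairwise_great_circle_km

__all__ = ["Mst", "Subtree", "NestedRegion", "build_mst", "split_subtrees",
           "enumerate_nested_regions", "screen_regions"]


@dataclass
class Mst:
    """Minimum spanning tree over a point set (great-circle metric)."""

    node_ids: list
    lons: np.ndarray
    lats: np.ndarray
    edges: list              # (i, j, km) index triples
    total_km: float
    dist: np.ndarray = field(repr=False, default=None)  # cached full matrix

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class Subtree:
    """Contiguous component of a global MST after cutting long branches."""

    indices: np.ndarray      # into the parent Mst arrays
    parent: Mst

    @property
    def node_ids(self) -> list:
        return [self.parent.node_ids[i] for i in self.indices]

    @property
    def n_nodes(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class NestedRegion:
    """One nested set of contiguous cells with its summed MST length."""

    cells: frozenset         # cell ids
    mst_km: float
    max_nn_km: float         # largest nearest-neighbour distance among members

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def build_mst(points, lon_col: str = "lon", lat_col: str = "lat",
              id_col: str = "cell_id") -> Mst:
    """Minimum spanning tree of a cell table under great-circle distance.

    ``points`` is a DataFrame with midpoint coordinates and cell ids.  The
    total weight is unique even when the tree topology is not (tied edges).
    """
    if len(points) < 2:
        raise ValueError(f"need >= 2 points to build an MST, got {len(points)}")
    lons = points[lon_col].to_numpy(dtype=float)
    lats = points[lat_col].to_numpy(dtype=float)
    ids = list(points[id_col]) if id_col in points.columns else list(range(len(points)))
    D = pairwise_great_circle_km(lons, lats)
    tree = _scipy_mst(csr_matrix(D)).tocoo()
    edges = [(int(i), int(j), float(w)) for i, j, w in zip(tree.row, tree.col, tree.data)]
    return Mst(node_ids=ids, lons=lons, lats=lats, edges=edges,
               total_km=float(tree.data.sum()), dist=D)


def split_subtrees(mst: Mst, cutoff_km: float = 1000.0, min_nodes: int = 10):
    """Cut MST branches longer than ``cutoff_km`` and return the resulting
    connected components with at least ``min_nodes`` nodes.

    Returns ``(subtrees, n_dropped_components)``.
    """
    n = mst.n_nodes
    adj = [[] for _ in range(n)]
    for i, j, w in mst.edges:
        if w <= cutoff_km:
            adj[i].append(j)
            adj[j].append(i)
    seen = np.zeros(n, dtype=bool)
    subtrees, dropped = [], 0
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        if len(comp) >= min_nodes:
            subtrees.append(Subtree(indices=np.array(sorted(comp)), parent=mst))
        else:
            dropped += 1
    subtrees.sort(key=lambda t: -t.n_nodes)
    return subtrees, dropped


def _accretion_orders(D: np.ndarray, rng: np.random.Generator, rel_tol: float = 1e-9):
    """Yield (order, accretion distances) for every starting point.

    At each step the point with minimum distance to the current set is added;
    exact-to-tolerance ties are broken uniformly at random with ``rng``.
    """
    n = D.shape[0]
    for start in range(n):
        in_set = np.zeros(n, dtype=bool)
        in_set[start] = True
        dmin = D[start].copy()
        order = [start]
        dists = np.empty(n - 1)
        for step in range(n - 1):
            dmin_masked = np.where(in_set, np.inf, dmin)
            best = dmin_masked.min()
            ties = np.flatnonzero(dmin_masked <= best * (1.0 + rel_tol))
            j = int(ties[0]) if ties.size == 1 else int(rng.choice(ties))
            order.append(j)
            dists[step] = dmin[j]
            in_set[j] = True
            np.minimum(dmin, D[j], out=dmin)
        yield order, dists


def enumerate_nested_regions(subtree: Subtree, seed: int = 0) -> list:
    """All unique nested regions of a contiguous subtree.

    Grows a nested sequence from every possible starting cell by
    single-linkage accretion, emits one region per growth step (sizes
    ``2..N``), and deduplicates by unordered cell set.  Ties in the
    nearest-point choice are broken by the seeded RNG.

    The MST length of each region accumulates along the growth path (Prim),
    and the maximum nearest-neighbour distance is maintained incrementally.
    """
    idx = subtree.indices
    if len(idx) < 2:
        raise ValueError("subtree must have >= 2 nodes")
    D = subtree.parent.dist[np.ix_(idx, idx)]
    ids = np.array(subtree.node_ids, dtype=object)
    rng = np.random.default_rng(seed)
    regions: dict = {}
    n = len(idx)
    for order, dists in _accretion_orders(D, rng):
        order_arr = np.asarray(order)
        nn = np.full(n, np.inf)
        mst_km = 0.0
        key = frozenset([order[0]])
        for step in range(1, n):
            j = order_arr[step]
            d = dists[step - 1]
            mst_km += d
            members = order_arr[:step]
            nn[members] = np.minimum(nn[members], D[members, j])
            nn[j] = d
            key = key | {j}
            max_nn = float(nn[order_arr[:step + 1]].max())
            if key not in regions:
                regions[key] = (mst_km, max_nn)
    out = []
    for key, (mst_km, max_nn) in regions.items():
        out.append(NestedRegion(cells=frozenset(ids[list(key)]),
                                mst_km=float(mst_km), max_nn_km=float(max_nn)))
    out.sort(key=lambda r: (r.n_cells, r.mst_km))
    return out


def screen_regions(regions, max_nn_km: float = 1000.0):
    """Drop regions whose loneliest member is >= ``max_nn_km`` from its
    nearest fellow member (strict ``<`` keeps).  Returns
    ``(kept, n_removed)``."""
    kept = [r for r in regions if r.max_nn_km < max_nn_km]
    return kept, len(regions) - len(kept)
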