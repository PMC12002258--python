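"""MST construction, subtree splitting and nested-region enumeration."""
import itertools

import numpy as np
import pandas as pd
import pytest

import paleosar as ps
from paleosar.grid import pairwise_great_circle_km
from paleosar.regions import build_mst, enumerate_nested_regions, screen_regions, split_subtrees

from conftest import random_points


def exhaustive_mst_total(D):
    """Minimum total weight over every spanning tree (Prufer enumeration).

    Independent oracle: enumerates all n**(n-2) labelled trees, so only
    usable for n <= 7.
    """
    n = D.shape[0]
    if n == 2:
        return D[0, 1]
    best = np.inf
    for code in itertools.product(range(n), repeat=n - 2):
        # decode Prufer sequence into an edge list
        degree = [1] * n
        for v in code:
            degree[v] += 1
        total = 0.0
        code_list = list(code)
        leaves = sorted(i for i in range(n) if degree[i] == 1)
        deg = degree[:]
        import heapq
        heapq.heapify(leaves)
        for v in code_list:
            leaf = heapq.heappop(leaves)
            total += D[leaf, v]
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(leaves, v)
        u = heapq.heappop(leaves)
        w = heapq.heappop(leaves)
        total += D[u, w]
        best = min(best, total)
    return best


def brute_force_accretion(D, seed=0):
    """Literal re-implementation of the nested-accretion rule (plain loops)."""
    rng = np.random.default_rng(seed)
    n = D.shape[0]
    found = set()
    for start in range(n):
        members = [start]
        while len(members) < n:
            dist_to_set = {j: min(D[i, j] for i in members)
                           for j in range(n) if j not in members}
            best = min(dist_to_set.values())
            cands = [j for j, d in sorted(dist_to_set.items())
                     if d <= best * (1 + 1e-9)]
            best_j = cands[0] if len(cands) == 1 else int(rng.choice(cands))
            members.append(best_j)
            found.add(frozenset(members))
    return found


def collinear_points():
    return pd.DataFrame({"cell_id": ["A", "B", "C"],
                         "lon": [0.0, 1.0, 3.0], "lat": [0.0, 0.0, 0.0]})


class TestBuildMst:
    def test_two_points_single_edge(self):
        pts = collinear_points().iloc[:2]
        mst = build_mst(pts)
        assert len(mst.edges) == 1
        assert mst.total_km == pytest.approx(ps.great_circle_km((0, 0), (1, 0)))

    def test_collinear_total(self):
        mst = build_mst(collinear_points())
        assert mst.total_km == pytest.approx(333.585, abs=1e-2)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            build_mst(collinear_points().iloc[:1])

    def test_matches_exhaustive_minimum_on_random_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            pts = random_points(rng, n)
            mst = build_mst(pts)
            D = pairwise_great_circle_km(pts["lon"].to_numpy(), pts["lat"].to_numpy())
            assert mst.total_km == pytest.approx(exhaustive_mst_total(D), rel=1e-9)


class TestSplitSubtrees:
    def test_no_long_edges_single_subtree(self):
        rng = np.random.default_rng(5)
        pts = random_points(rng, 12, lon_span=3.0, lat_span=2.0)  # compact cloud
        mst = build_mst(pts)
        assert max(w for _, _, w in mst.edges) < 1000.0
        subtrees, dropped = split_subtrees(mst, cutoff_km=1000.0, min_nodes=10)
        assert dropped == 0
        assert len(subtrees) == 1 and subtrees[0].n_nodes == 12

    def test_two_small_clusters_both_dropped(self):
        # 6 + 6 points, clusters ~2,000 km apart: both components < 10 nodes
        lons = np.concatenate([np.linspace(0, 1, 6), np.linspace(18, 19, 6)])
        pts = pd.DataFrame({"cell_id": [f"c{i}" for i in range(12)],
                            "lon": lons, "lat": np.zeros(12)})
        subtrees, dropped = split_subtrees(build_mst(pts), 1000.0, 10)
        assert subtrees == [] and dropped == 2

    def test_15_and_10_node_clusters_split(self):
        lons = np.concatenate([np.linspace(0, 7, 15), np.linspace(20.5, 25, 10)])
        pts = pd.DataFrame({"cell_id": [f"c{i}" for i in range(25)],
                            "lon": lons, "lat": np.zeros(25)})
        subtrees, dropped = split_subtrees(build_mst(pts), 1000.0, 10)
        assert sorted(t.n_nodes for t in subtrees) == [10, 15]
        assert dropped == 0


class TestEnumerate:
    def test_collinear_unique_regions(self):
        mst = build_mst(collinear_points())
        st = split_subtrees(mst, 1000.0, 2)[0][0]
        regions = enumerate_nested_regions(st, seed=0)
        sets = {r.cells for r in regions}
        assert sets == {frozenset("AB"), frozenset("BC"), frozenset("ABC")}

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(3, 6))
            pts = random_points(rng, n)
            mst = build_mst(pts)
            st = split_subtrees(mst, 1e9, 2)[0][0]
            regions = enumerate_nested_regions(st, seed=1)
            got = {frozenset(int(c[1:]) for c in r.cells) for r in regions}
            D = pairwise_great_circle_km(pts["lon"].to_numpy(), pts["lat"].to_numpy())
            assert got == brute_force_accretion(D)

    def test_ring_of_equidistant_points_bounded(self):
        # points on a small circle: tie-heavy geometry; unique regions are
        # bounded by N*(N-1) growth steps before dedupe
        n = 8
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = pd.DataFrame({"cell_id": [f"r{i}" for i in range(n)],
                            "lon": 3.0 * np.cos(ang), "lat": 3.0 * np.sin(ang)})
        st = split_subtrees(build_mst(pts), 1e9, 2)[0][0]
        regions = enumerate_nested_regions(st, seed=4)
        assert 2 <= len(regions) <= n * (n - 1)
        assert any(r.n_cells == n for r in regions)

    def test_mst_monotone_along_nesting(self):
        rng = np.random.default_rng(8)
        pts = random_points(rng, 12)
        st = split_subtrees(build_mst(pts), 1e9, 2)[0][0]
        regions = enumerate_nested_regions(st, seed=0)
        by_set = {r.cells: r.mst_km for r in regions}
        for r1 in regions:
            for r2 in regions:
                if r1.cells < r2.cells:
                    assert by_set[r1.cells] <= by_set[r2.cells] + 1e-9

    def test_seed_invariant_without_ties(self):
        rng = np.random.default_rng(33)
        pts = random_points(rng, 10)
        st = split_subtrees(build_mst(pts), 1e9, 2)[0][0]
        a = {r.cells for r in enumerate_nested_regions(st, seed=1)}
        b = {r.cells for r in enumerate_nested_regions(st, seed=99)}
        assert a == b


class TestScreen:
    def test_close_pair_kept(self):
        r = ps.NestedRegion(cells=frozenset("ab"), mst_km=500.0, max_nn_km=500.0)
        kept, removed = screen_regions([r], 1000.0)
        assert kept == [r] and removed == 0

    def test_lonely_cell_removed(self):
        r = ps.NestedRegion(cells=frozenset("abc"), mst_km=2000.0, max_nn_km=1200.0)
        kept, removed = screen_regions([r], 1000.0)
        assert kept == [] and removed == 1

    def test_mixed_fixture_counts(self):
        regions = [ps.NestedRegion(frozenset({f"x{i}", f"y{i}"}), 100.0 * i,
                                   max_nn_km=1500.0 if i < 3 else 400.0)
                   for i in range(10)]
        kept, removed = screen_regions(regions, 1000.0)
        assert len(kept) == 7 and removed == 3

    def test_threshold_is_strict(self):
        r = ps.NestedRegion(frozenset("ab"), 1000.0, max_nn_km=1000.0)
        kept, _ = screen_regions([r], 1000.0)
        assert kept == []
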