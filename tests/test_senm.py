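"""Spatially explicit neutral model: sampler, oracle, fossilization."""
import numpy as np
import pandas as pd
import pytest

from paleosar.senm import (NeutralParams, ewens_expected_richness, forward_oracle,
                           fossilize, simulate_neutral_sample)
from paleosar.synthetic import generate_occurrence_table_from_senm


def tiny_params(**kw):
    base = dict(nu=0.05, dispersal_sigma=100.0, landscape=(5, 5, 100.0), density=10)
    base.update(kw)
    return NeutralParams(**base)


class TestParams:
    def test_nu_zero_rejected(self):
        with pytest.raises(ValueError, match="nu"):
            NeutralParams(nu=0.0)

    def test_bad_kernel_rejected(self):
        with pytest.raises(ValueError):
            NeutralParams(nu=0.1, kernel="levy")


class TestSampler:
    def test_nu_one_every_individual_distinct(self):
        a = simulate_neutral_sample(tiny_params(nu=1.0), [(0, 0), (2, 2)], 5, seed=1)
        assert a.richness() == 10

    def test_single_individual_single_species(self):
        a = simulate_neutral_sample(tiny_params(), [(1, 1)], 1, seed=2)
        assert a.richness() == 1

    def test_sample_outside_landscape_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_neutral_sample(tiny_params(), [(9, 0)], 1, seed=0)

    def test_cannot_oversample_a_cell(self):
        with pytest.raises(ValueError):
            simulate_neutral_sample(tiny_params(density=3), [(0, 0)], 5, seed=0)

    def test_seed_reproducible(self):
        p = tiny_params()
        cells = [(0, 0), (1, 2), (3, 4)]
        a = simulate_neutral_sample(p, cells, 4, seed=9)
        b = simulate_neutral_sample(p, cells, 4, seed=9)
        assert a.cells == b.cells

    def test_counts_sum_to_sample_size(self):
        a = simulate_neutral_sample(tiny_params(), [(0, 0), (4, 4)], 7, seed=3)
        for cell, counter in a.cells.items():
            assert sum(counter.values()) == 7

    def test_richness_monotone_in_nu(self):
        cells = [(i, j) for i in range(5) for j in range(5)]
        means = []
        for nu in (0.01, 0.2):
            vals = [simulate_neutral_sample(tiny_params(nu=nu), cells, 2,
                                            seed=100 * int(nu * 1000) + s).richness()
                    for s in range(25)]
            means.append(np.mean(vals))
        assert means[0] < means[1]


class TestForwardOracle:
    def test_large_lattice_refused(self):
        with pytest.raises(ValueError, match="desk-scale"):
            forward_oracle(NeutralParams(nu=0.1, landscape=(20, 20, 100.0),
                                         density=5), 10)

    def test_nu_one_all_distinct(self):
        sampler = forward_oracle(tiny_params(nu=1.0), generations=5, seed=0)
        a = sampler([(0, 0), (1, 1)], 3, sample_seed=1)
        assert a.richness() == 6

    def test_richness_increases_with_nu_forward(self):
        cells = [(i, j) for i in range(5) for j in range(5)]
        means = []
        for nu in (0.01, 0.1):
            vals = []
            for s in range(8):
                sampler = forward_oracle(tiny_params(nu=nu), generations=150,
                                         seed=50 + s)
                vals.append(sampler(cells, 2, sample_seed=s).richness())
            means.append(np.mean(vals))
        assert means[0] < means[1]


class TestEwens:
    def test_formula_small_cases(self):
        assert ewens_expected_richness(2.0, 1) == 1.0
        # n=2: 1 + theta/(theta+1)
        assert ewens_expected_richness(1.0, 2) == pytest.approx(1.5)


class TestFossilize:
    def make_assemblage(self):
        return simulate_neutral_sample(tiny_params(nu=0.2, density=30),
                                       [(0, 0), (2, 2), (4, 4)], 30, seed=5)

    def test_single_cell_template_row_count(self):
        a = self.make_assemblage()
        tpl = pd.DataFrame([{"cell_x": 0, "cell_y": 0, "collection": 1, "n_occ": 7}])
        occ = fossilize(a, tpl, seed=1)
        assert len(occ) == 7
        assert occ["collection_no"].nunique() == 1

    def test_total_occurrences_conserved(self):
        a = self.make_assemblage()
        tpl = pd.DataFrame([
            {"cell_x": 0, "cell_y": 0, "collection": 1, "n_occ": 5},
            {"cell_x": 2, "cell_y": 2, "collection": 2, "n_occ": 9},
            {"cell_x": 4, "cell_y": 4, "collection": 3, "n_occ": 2},
        ])
        occ = fossilize(a, tpl, seed=1)
        assert len(occ) == tpl["n_occ"].sum()

    def test_halved_template_halves_output(self):
        a = self.make_assemblage()
        tpl = pd.DataFrame([{"cell_x": 0, "cell_y": 0, "collection": 1, "n_occ": 20}])
        half = tpl.assign(n_occ=tpl["n_occ"] // 2)
        assert len(fossilize(a, half, seed=1)) * 2 == len(fossilize(a, tpl, seed=1))

    def test_template_cell_outside_landscape_rejected(self):
        a = self.make_assemblage()
        tpl = pd.DataFrame([{"cell_x": 7, "cell_y": 0, "collection": 1, "n_occ": 3}])
        with pytest.raises(ValueError, match="outside"):
            fossilize(a, tpl, seed=0)

    def test_species_drawn_from_cell_pool(self):
        a = self.make_assemblage()
        tpl = pd.DataFrame([{"cell_x": 2, "cell_y": 2, "collection": 1, "n_occ": 12}])
        occ = fossilize(a, tpl, seed=2)
        pool = {f"Neutralus sp{s}" for s in a.cells[(2, 2)]}
        assert set(occ["accepted_name"]) <= pool


class TestSenmTableGenerator:
    def test_nu_one_distinct_species(self):
        p = NeutralParams(nu=1.0, landscape=(6, 6, 100.0), density=20)
        occ = generate_occurrence_table_from_senm(
            p, {"n_cells": 2, "collections_per_cell": 1, "occ_per_collection": 10},
            seed=0)
        assert len(occ) == 20

    def test_fixed_seed_byte_identical(self, tmp_path):
        p = NeutralParams(nu=0.1, landscape=(6, 6, 100.0), density=20)
        spec = {"n_cells": 4, "collections_per_cell": 2, "occ_per_collection": 6}
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_occurrence_table_from_senm(p, spec, seed=3).to_csv(f1, index=False)
        generate_occurrence_table_from_senm(p, spec, seed=3).to_csv(f2, index=False)
        assert f1.read_bytes() == f2.read_bytes()

    def test_different_seeds_same_shape_different_content(self):
        p = NeutralParams(nu=0.1, landscape=(6, 6, 100.0), density=20)
        spec = {"n_cells": 4, "collections_per_cell": 2, "occ_per_collection": 6}
        a = generate_occurrence_table_from_senm(p, spec, seed=1)
        b = generate_occurrence_table_from_senm(p, spec, seed=2)
        assert len(a) == len(b) == 48
        assert not a["accepted_name"].equals(b["accepted_name"])
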