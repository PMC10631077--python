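import numpy as np
import pytest

import ccitensor as ct
from ccitensor.simulate import PHI_FLOOR


class TestNbParamEstimation:
    def test_direct_formula(self):
        # gene with m=2, v=6 -> phi = (6-2)/4 = 1
        values = np.array([[0.0, 1.0, 2.0, 3.0, 4.0]])  # m=2, v=2.5 -- build explicit
        expr = ct.ExpressionMatrix(values, ["g"], [f"c{i}" for i in range(5)])
        est = ct.estimate_nb_params(expr)
        m, v = values.mean(), values.var(ddof=1)
        assert est.phi[0] == pytest.approx((v - m) / m**2)

    def test_underdispersed_gene_floored_and_flagged(self):
        values = np.array([[1.0, 1.0, 1.0, 1.0]])  # v=0 <= m
        est = ct.estimate_nb_params(ct.ExpressionMatrix(values, ["g"], list("abcd")))
        assert est.phi[0] == PHI_FLOOR and est.clamped[0]

    def test_moments_match_loop_oracle(self, rng):
        values = rng.uniform(0, 10, size=(20, 30))
        expr = ct.ExpressionMatrix(values, [f"g{i}" for i in range(20)], [f"c{h}" for h in range(30)])
        est = ct.estimate_nb_params(expr)
        for i in range(20):
            assert est.m[i] == pytest.approx(sum(values[i]) / 30)
            assert est.v[i] == pytest.approx(
                sum((x - est.m[i]) ** 2 for x in values[i]) / 29
            )

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            ct.estimate_nb_params(ct.ExpressionMatrix([[1.0]], ["g"], ["a"]))


class TestDefaultNbParams:
    def test_reproducible_and_positive(self):
        a = ct.default_nb_params(100, seed=3)
        b = ct.default_nb_params(100, seed=3)
        np.testing.assert_array_equal(a.m, b.m)
        assert np.all(a.m > 0) and np.all(a.phi > 0)

    def test_distribution_moments_at_large_n(self):
        p = ct.default_nb_params(100_000, seed=0)
        assert np.log10(p.m).mean() == pytest.approx(0.5, rel=0.05)
        assert np.log10(p.m).std() == pytest.approx(0.7, rel=0.05)
        assert p.phi.mean() == pytest.approx(0.5, rel=0.05)  # gamma(2, 0.25)


class TestFoldChange:
    def test_zero_amplitude_gives_unit_fold(self):
        model = ct.FoldChangeModel(0.0, 0.5)
        assert ct.fold_change(7.3, model) == 1.0

    def test_e10_at_zero_mean(self):
        model = ct.FoldChangeModel.from_name("E10")
        assert ct.fold_change(0.0, model) == pytest.approx(10.0**4.429)

    def test_e2_at_zero_mean(self):
        model = ct.FoldChangeModel.from_name("E2")
        assert ct.fold_change(0.0, model) == pytest.approx(10.0**0.701)

    def test_strictly_decreasing_in_mean(self):
        model = ct.FoldChangeModel.from_name("E5")
        m = np.linspace(0, 50, 100)
        assert np.all(np.diff(ct.fold_change(m, model)) < 0)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            ct.fold_change(-1.0, ct.FoldChangeModel.from_name("E2"))


class TestDropout:
    def test_zero_mean_always_dropped(self):
        assert ct.dropout_probability(1.0, 0.0) == 1.0

    def test_direct_value(self):
        assert ct.dropout_probability(1.0, 1.0, 1.0) == pytest.approx(np.exp(-1))

    def test_monotone_in_mean_and_c(self):
        m = np.linspace(0, 5, 50)
        assert np.all(np.diff(ct.dropout_probability(1.0, m)) <= 0)
        assert ct.dropout_probability(1.0, 2.0, c=2.0) <= ct.dropout_probability(1.0, 2.0, c=1.0)


class TestCciPatterns:
    def test_one_to_one_single_block(self):
        cfg = ct.SimulationConfig(n_celltypes=3, cci_style="one-to-one", n_cci_types=1,
                                  n_genes=100, n_lr_pairs=20, seed=0)
        pats = ct.make_cci_patterns(cfg)
        assert len(pats) == 1
        assert len(pats[0].ligand_celltypes) == 1 and len(pats[0].receptor_celltypes) == 1

    def test_pair_blocks_disjoint(self):
        cfg = ct.SimulationConfig(n_celltypes=5, cci_style="many-to-many", n_cci_types=5,
                                  n_genes=200, n_lr_pairs=60, seed=1)
        pats = ct.make_cci_patterns(cfg)
        blocks = [set(p.pair_indices) for p in pats]
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                assert not blocks[i] & blocks[j]

    def test_many_to_many_truth_count(self):
        # |S|=2, |T|=3, 5 pairs -> 30 truth entries
        cfg = ct.SimulationConfig(n_celltypes=6, n_cci_types=1, n_genes=100, n_lr_pairs=10,
                                  seed=0, pattern_spec=[([0, 1], [2, 3, 4])])
        ds = ct.simulate_dataset(cfg)
        assert ds.truth.sum() == 2 * 3 * 5

    def test_too_many_cci_types_rejected(self):
        cfg = ct.SimulationConfig(n_celltypes=3, n_cci_types=5, n_genes=100, n_lr_pairs=4, seed=0)
        with pytest.raises(ValueError, match="not enough"):
            ct.make_cci_patterns(cfg)


class TestSimulateDataset:
    def test_no_cci_types_gives_null_dataset(self):
        cfg = ct.SimulationConfig(n_celltypes=3, n_cci_types=0, n_genes=60, n_lr_pairs=10, seed=0)
        ds = ct.simulate_dataset(cfg)
        assert ds.truth.sum() == 0
        assert np.all(ds.deg_table == 1.0)

    def test_same_seed_bit_identical(self):
        cfg = ct.SimulationConfig(n_celltypes=3, n_genes=80, n_cells_per_type=10,
                                  n_lr_pairs=15, seed=9)
        a, b = ct.simulate_dataset(cfg), ct.simulate_dataset(cfg)
        np.testing.assert_array_equal(a.counts.values, b.counts.values)
        np.testing.assert_array_equal(a.truth, b.truth)
        assert a.pairs.pairs == b.pairs.pairs

    def test_counts_are_non_negative_integers(self, small_dataset):
        v = small_dataset.counts.values
        assert np.all(v >= 0) and np.all(v == np.round(v))

    def test_truth_is_union_of_planted_blocks(self, small_dataset):
        J, K = small_dataset.truth.shape[0], small_dataset.truth.shape[2]
        expected = np.zeros((J, J, K))
        for pat in small_dataset.patterns:
            for s in pat.ligand_celltypes:
                for t in pat.receptor_celltypes:
                    for k in pat.pair_indices:
                        expected[s, t, k] = 1
        np.testing.assert_array_equal(small_dataset.truth, expected)

    def test_deg_mean_matches_analytic_nb_mean(self):
        # no dropout, many cells: empirical DEG-gene mean within 3 SE of f*m
        cfg = ct.SimulationConfig(n_celltypes=2, n_cci_types=1, threshold_name="E5",
                                  n_genes=40, n_cells_per_type=2000, n_lr_pairs=5,
                                  dropout=False, seed=4, pattern_spec=[([0], [1])])
        ds = ct.simulate_dataset(cfg)
        pat = ds.patterns[0]
        k = pat.pair_indices[0]
        lig = ds.pairs.pairs[k][0]
        gi = ds.counts.gene_ids.index(lig)
        f = ds.deg_table[gi, 0]
        assert f > 1.0
        params = ct.default_nb_params(cfg.n_genes, seed=cfg.seed)
        mean_expected = f * params.m[gi]
        cells = ds.counts.values[gi, :2000]  # cell type 0 block
        var = mean_expected + params.phi[gi] * mean_expected**2
        se = np.sqrt(var / 2000)
        assert abs(cells.mean() - mean_expected) <= 3 * se

    def test_dropout_increases_zero_fraction(self):
        base = dict(n_celltypes=2, n_cci_types=0, n_genes=100, n_cells_per_type=200,
                    n_lr_pairs=10, seed=6)
        with_do = ct.simulate_dataset(ct.SimulationConfig(dropout=True, **base))
        without = ct.simulate_dataset(ct.SimulationConfig(dropout=False, **base))
        assert (with_do.counts.values == 0).mean() > (without.counts.values == 0).mean()

    def test_nb_variance_mean_relationship(self):
        # empirical var/mean matches 1 + phi * mean within 10% at n = 1e4
        n = 10_000
        for phi in (0.1, 1.0, 4.0):
            params = ct.NBGeneParams(m=np.array([5.0]), phi=np.array([phi]))
            cfg = ct.SimulationConfig(n_celltypes=1, n_cci_types=0, n_genes=1,
                                      n_cells_per_type=n, n_lr_pairs=0, dropout=False,
                                      seed=int(phi * 10))
            # n_lr_pairs=0 is invalid for detection but fine for raw sampling
            cfg.n_lr_pairs = 0
            ds = ct.simulate_dataset(cfg, params=params)
            x = ds.counts.values[0]
            ratio = x.var(ddof=1) / x.mean()
            assert ratio == pytest.approx(1 + phi * x.mean(), rel=0.10)


class TestPaperDesign:
    def test_ninety_distinct_configs(self):
        configs = ct.enumerate_paper_configs(seed_base=0)
        assert len(configs) == 90
        keys = {(c.n_celltypes, c.cci_style, c.n_cci_types, c.threshold_name) for c in configs}
        assert len(keys) == 90

    def test_seeds_distinct_and_reproducible(self):
        a = ct.enumerate_paper_configs(seed_base=5)
        b = ct.enumerate_paper_configs(seed_base=5)
        assert [c.seed for c in a] == [c.seed for c in b]
        assert len({c.seed for c in a}) == 90
        assert all(0 <= c.seed < 2**31 for c in a)

    def test_factor_levels(self):
        configs = ct.enumerate_paper_configs()
        assert {c.n_celltypes for c in configs} == {3, 5, 10, 20, 30}
        assert {c.cci_style for c in configs} == {"one-to-one", "many-to-many"}
        assert {c.n_cci_types for c in configs} == {1, 3, 5}
        assert {c.threshold_name for c in configs} == {"E2", "E5", "E10"}
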