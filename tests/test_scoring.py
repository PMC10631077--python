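import itertools

import numpy as np
import pytest

import ccitensor as ct


class TestScores:
    def test_sum_and_product_direct_values(self):
        xl, xr = np.array([2.0, 0.0]), np.array([3.0, 0.0])
        assert ct.sum_score(xl, xr)[0, 0] == 5.0
        assert ct.product_score(xl, xr)[0, 0] == 6.0
        assert ct.sum_score(np.zeros(2), np.zeros(2)).sum() == 0
        assert ct.product_score(np.zeros(2), xr).sum() == 0

    def test_sum_and_product_match_double_loop(self, rng):
        xl, xr = rng.uniform(0, 5, 4), rng.uniform(0, 5, 4)
        for s, t in itertools.product(range(4), range(4)):
            assert ct.sum_score(xl, xr)[s, t] == pytest.approx(xl[s] + xr[t])
            assert ct.product_score(xl, xr)[s, t] == pytest.approx(xl[s] * xr[t])

    def test_halpern_zero_at_both_means(self):
        # middle cell type sits exactly at the mean of (1,2,3)
        S = ct.halpern_score(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert S[1, 1] == pytest.approx(0.0)

    def test_halpern_hand_z_scaling(self):
        # sample sd of (1,2,3) is 1, so Z = (-1, 0, 1) and S[2,2] = sqrt(2)
        S = ct.halpern_score(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert S[2, 2] == pytest.approx(np.sqrt(2))

    def test_halpern_symmetric_for_equal_inputs(self, rng):
        x = rng.uniform(0, 5, 5)
        S = ct.halpern_score(x, x)
        np.testing.assert_allclose(S, S.T, atol=1e-12)

    def test_halpern_affine_invariant(self, rng):
        xl, xr = rng.uniform(0, 5, 6), rng.uniform(0, 5, 6)
        S = ct.halpern_score(xl, xr)
        np.testing.assert_allclose(ct.halpern_score(3 * xl + 2, 0.5 * xr + 9), S, atol=1e-9)

    def test_halpern_zero_variance_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            S = ct.halpern_score(np.full(3, 2.0), np.array([1.0, 2, 3]))
        # score collapses to |Z| of the receptor side
        np.testing.assert_allclose(S[0], [1, 0, 1], atol=1e-12)

    def test_cabello_aguilar_values_and_bounds(self, rng):
        assert ct.cabello_aguilar_score(np.array([2.0]), np.array([2.0]), mu=2.0)[0, 0] == 0.5
        assert ct.cabello_aguilar_score(np.array([0.0]), np.array([5.0]), mu=1.0)[0, 0] == 0.0
        xl, xr = rng.uniform(0, 5, 4), rng.uniform(0, 5, 4)
        S = ct.cabello_aguilar_score(xl, xr, mu=0.7)
        assert np.all((S >= 0) & (S < 1))
        with pytest.raises(ValueError):
            ct.cabello_aguilar_score(xl, xr, mu=0.0)

    def test_compute_mu(self):
        expr = ct.ExpressionMatrix([[0.0, 2.0], [4.0, 6.0]], ["g1", "g2"], ["a", "b"])
        assert ct.compute_mu(expr) == 3.0


class TestScoreAllPairs:
    def test_product_tensor_equals_cci_tensor(self, small_dataset):
        norm = ct.log_transform(ct.normalize_cpmed(small_dataset.counts))
        st = ct.score_all_pairs(norm, small_dataset.labels, small_dataset.pairs, "product")
        X = ct.average_by_celltype(norm, small_dataset.labels)
        chi = ct.build_cci_tensor(X, small_dataset.pairs)
        np.testing.assert_array_equal(st.values, chi.values)

    def test_single_pair_reduces_to_per_pair_op(self, tiny_expr, tiny_labels):
        pairs = ct.LRPairTable([("gL", "gR")])
        st = ct.score_all_pairs(tiny_expr, tiny_labels, pairs, "sum")
        xl = ct.celltype_mean(tiny_expr, tiny_labels, "gL")
        xr = ct.celltype_mean(tiny_expr, tiny_labels, "gR")
        np.testing.assert_allclose(st.values[:, :, 0], ct.sum_score(xl, xr))

    @pytest.mark.parametrize("method", ["sum", "product", "halpern", "cabello_aguilar"])
    def test_invariant_to_cell_order_within_type(self, small_dataset, method):
        norm = ct.log_transform(ct.normalize_cpmed(small_dataset.counts))
        st = ct.score_all_pairs(norm, small_dataset.labels, small_dataset.pairs, method)
        # shuffle cells globally; labels travel with the cells
        rng = np.random.default_rng(0)
        perm = rng.permutation(norm.n_cells)
        shuffled = ct.ExpressionMatrix(
            norm.values[:, perm], norm.gene_ids, [norm.cell_ids[i] for i in perm]
        )
        st2 = ct.score_all_pairs(shuffled, small_dataset.labels, small_dataset.pairs, method)
        np.testing.assert_allclose(st2.values, st.values, atol=1e-9)

    def test_unknown_method_rejected(self, tiny_expr, tiny_labels):
        with pytest.raises(ValueError, match="unknown method"):
            ct.score_all_pairs(tiny_expr, tiny_labels, ct.LRPairTable([("gL", "gR")]), "bogus")


class TestPermutationTest:
    def test_identical_cells_give_p_one(self):
        expr = ct.ExpressionMatrix(np.ones((2, 4)), ["gL", "gR"], list("abcd"))
        labels = ct.CellTypeLabels({"a": "A", "b": "A", "c": "B", "d": "B"})
        pr = ct.permutation_test(expr, labels, ct.LRPairTable([("gL", "gR")]), "sum", P=50, seed=0)
        np.testing.assert_array_equal(pr.pvalues, 1.0)

    def test_deterministic_given_seed(self, tiny_expr, tiny_labels):
        pairs = ct.LRPairTable([("gL", "gR")])
        a = ct.permutation_test(tiny_expr, tiny_labels, pairs, "product", P=100, seed=5)
        b = ct.permutation_test(tiny_expr, tiny_labels, pairs, "product", P=100, seed=5)
        np.testing.assert_array_equal(a.pvalues, b.pvalues)

    def test_matches_exhaustive_enumeration(self):
        # 4 cells, 2 types: 4!/(2!2!) = 6 distinct assignments
        expr = ct.ExpressionMatrix(
            [[1.0, 5.0, 2.0, 0.0], [3.0, 1.0, 4.0, 2.0]], ["gL", "gR"], list("abcd")
        )
        labels = ct.CellTypeLabels({"a": "T1", "b": "T1", "c": "T2", "d": "T2"})
        pairs = ct.LRPairTable([("gL", "gR")])
        obs = ct.score_all_pairs(expr, labels, pairs, "sum").values
        A = labels.indicator(list("abcd"))
        exhaustive = np.zeros_like(obs)
        n = 0
        for perm in itertools.permutations(range(4)):
            means = expr.values @ A[list(perm)]
            s = means[0][:, None] + means[1][None, :]
            exhaustive += s[:, :, None] >= obs
            n += 1
        exhaustive /= n
        P = 20000
        pr = ct.permutation_test(expr, labels, pairs, "sum", P=P, seed=3)
        se = np.sqrt(exhaustive * (1 - exhaustive) / P)
        assert np.all(np.abs(pr.pvalues - exhaustive) <= 3 * np.maximum(se, 1e-12))

    def test_strictly_dominant_observed_gives_p_zero(self):
        # 10 cells per type, perfect separation: no sampled shuffle can
        # reproduce the observed grouping, so the exceedance set is empty
        H = 20
        values = np.zeros((2, H))
        values[:, :10] = 100.0
        cells = [f"c{i}" for i in range(H)]
        expr = ct.ExpressionMatrix(values, ["gL", "gR"], cells)
        labels = ct.CellTypeLabels({c: ("A" if i < 10 else "B") for i, c in enumerate(cells)})
        pr = ct.permutation_test(expr, labels, ct.LRPairTable([("gL", "gR")]), "product", P=200, seed=0)
        assert pr.pvalues[0, 0, 0] == 0.0  # (A, A): observed is strictly maximal
        assert pr.pvalues[1, 1, 0] == 1.0  # (B, B): observed is minimal

    def test_invalid_arguments_rejected(self, tiny_expr, tiny_labels):
        pairs = ct.LRPairTable([("gL", "gR")])
        with pytest.raises(ValueError):
            ct.permutation_test(tiny_expr, tiny_labels, pairs, "sum", P=0)
        one_type = ct.CellTypeLabels({c: "A" for c in tiny_expr.cell_ids})
        with pytest.raises(ValueError, match="2 cell types"):
            ct.permutation_test(tiny_expr, one_type, pairs, "sum", P=10)


class TestBinarizeByPvalue:
    def test_threshold_behaviour(self):
        pr = ct.PermutationResult(
            np.array([[[0.0, 0.04, 0.05, 1.0]]]), 100, 0, "sum", ["A"], [("l", "r")] * 4
        )
        np.testing.assert_array_equal(ct.binarize_by_pvalue(pr, 0.05), [[[1, 1, 0, 0]]])
        np.testing.assert_array_equal(ct.binarize_by_pvalue(pr, 0.0), [[[0, 0, 0, 0]]])

    def test_count_matches_loop_oracle(self, rng):
        p = rng.uniform(0, 1, (3, 3, 5))
        pr = ct.PermutationResult(p, 100, 0, "sum", ["A", "B", "C"], [("l", "r")] * 5)
        pred = ct.binarize_by_pvalue(pr, 0.3)
        assert pred.sum() == sum(1 for v in p.ravel() if v < 0.3)
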