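import numpy as np
import pandas as pd
import pytest

from contextnet import (
    ContextMask,
    DifferentialNetwork,
    FitnessMatrix,
    bootstrap_null,
    classify_edges,
    correlation_matrix,
    dpcc_for_context,
    empirical_pvalues,
    make_null_dataset,
    quantile_normalize,
    summarize_features,
)
from contextnet.diffnet import BootstrapNull, DpccResult


def _fm(values, genes=None, lines=None, normalized=False):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    lines = lines or [f"CL{i}" for i in range(arr.shape[1])]
    return FitnessMatrix(pd.DataFrame(arr, index=genes, columns=lines), normalized=normalized)


class TestQuantileNormalize:
    def test_single_column_is_identity(self):
        fm = _fm([[3.0], [1.0], [2.0]])
        out = quantile_normalize(fm)
        np.testing.assert_array_equal(out.values.to_numpy(), fm.values.to_numpy())
        assert out.normalized

    def test_identical_columns_unchanged(self):
        col = [5.0, -2.0, 0.5, 9.0]
        fm = _fm(np.column_stack([col, col]))
        out = quantile_normalize(fm)
        np.testing.assert_allclose(out.values.to_numpy(), fm.values.to_numpy())

    def test_4x2_toy_matches_hand_computed_rank_means(self):
        # columns [1,2,3,4] and [4,3,2,1]: rank-r mean is (r-th smallest of each)
        # = (1+1, 2+2, 3+3, 4+4)/2 = 1,2,3,4; so each column maps back to its own ranks
        fm = _fm([[1.0, 4.0], [2.0, 3.0], [3.0, 2.0], [4.0, 1.0]])
        out = quantile_normalize(fm).values.to_numpy()
        np.testing.assert_allclose(out, [[1, 4], [2, 3], [3, 2], [4, 1]])

    def test_columns_share_sorted_values_exactly(self):
        rng = np.random.default_rng(0)
        fm = _fm(rng.normal(size=(30, 5)))
        out = quantile_normalize(fm).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_array_equal(np.sort(out[:, j]), ref)

    def test_idempotent_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        fm = _fm(rng.normal(size=(25, 4)))
        once = quantile_normalize(fm)
        with pytest.warns(UserWarning, match="already"):
            twice = quantile_normalize(once)
        np.testing.assert_array_equal(once.values.to_numpy(), twice.values.to_numpy())

    def test_ties_get_mean_of_rank_means_over_span(self):
        # column 0 has a tie at ranks 0-1; reference is the cross-column rank mean
        fm = _fm([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(fm).values.to_numpy()
        ref = [(1 + 10) / 2, (1 + 20) / 2, (5 + 30) / 2]  # 5.5, 10.5, 17.5
        np.testing.assert_allclose(out[:, 1], ref)
        np.testing.assert_allclose(out[:2, 0], [(5.5 + 10.5) / 2] * 2)  # tied span mean
        np.testing.assert_allclose(out[2, 0], 17.5)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_closed_forms(self):
        base = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        fm = _fm(np.vstack([base, base * 2 + 1, -base]), normalized=True)
        cm = correlation_matrix(fm)
        np.testing.assert_allclose(np.diag(cm.values), 1.0)
        assert cm.values[0, 1] == pytest.approx(1.0)
        assert cm.values[0, 2] == pytest.approx(-1.0)

    def test_matches_naive_two_pass_covariance_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 8))
        fm = _fm(X, normalized=True)
        cm = correlation_matrix(fm).values
        for i in range(5):
            for j in range(5):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(cm[i, j] - expected) < 1e-12

    def test_zero_variance_gene_flagged_with_zero_correlations(self):
        X = np.vstack([np.ones(6), np.arange(6.0)])
        cm = correlation_matrix(_fm(X, normalized=True))
        assert cm.zero_variance == ("G0",)
        assert cm.values[0, 1] == 0.0
        assert cm.values[0, 0] == 1.0

    def test_requires_normalized_matrix(self):
        with pytest.raises(ValueError, match="normalized"):
            correlation_matrix(_fm(np.random.default_rng(0).normal(size=(3, 5))))

    def test_exclusion_needs_three_remaining_lines(self):
        fm = _fm(np.random.default_rng(1).normal(size=(3, 4)), normalized=True)
        mask = ContextMask("big", np.array([True, True, False, False]))
        with pytest.raises(ValueError, match="3 cell lines"):
            correlation_matrix(fm, exclude=mask)


class TestDpcc:
    def test_dpcc_is_elementwise_difference(self):
        rng = np.random.default_rng(5)
        fm = quantile_normalize(_fm(rng.normal(size=(6, 20))))
        mask = ContextMask("ctx", np.arange(20) < 5)
        res = dpcc_for_context(fm, mask)
        np.testing.assert_allclose(res.dpcc, res.pcc_all.values - res.pcc_excl.values, atol=1e-9)

    def test_duplicate_profile_blocks_give_zero_dpcc(self):
        # context lines duplicate non-context lines exactly: excluding them
        # leaves every pairwise correlation unchanged
        rng = np.random.default_rng(6)
        half = rng.normal(size=(5, 10))
        fm = _fm(np.hstack([half, half]), normalized=True)
        mask = ContextMask("dup", np.arange(20) >= 10)
        res = dpcc_for_context(fm, mask)
        np.testing.assert_allclose(res.dpcc, 0.0, atol=1e-12)

    def test_planted_context_correlation_yields_positive_dpcc(self):
        rng = np.random.default_rng(7)
        n, n_ctx = 150, 30
        z = rng.normal(size=n_ctx)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a[:n_ctx] = np.sqrt(0.8) * z + np.sqrt(0.2) * rng.normal(size=n_ctx)
        b[:n_ctx] = np.sqrt(0.8) * z + np.sqrt(0.2) * rng.normal(size=n_ctx)
        fm = _fm(np.vstack([a, b, rng.normal(size=n)]), normalized=True)
        res = dpcc_for_context(fm, ContextMask("ctx", np.arange(n) < n_ctx))
        # oracle: recompute both correlations directly
        direct_all = np.corrcoef(a, b)[0, 1]
        direct_excl = np.corrcoef(a[n_ctx:], b[n_ctx:])[0, 1]
        assert res.dpcc[0, 1] == pytest.approx(direct_all - direct_excl, abs=1e-12)
        assert res.dpcc[0, 1] > 0

    def test_mask_must_flag_at_least_one_line(self):
        with pytest.raises(ValueError, match="at least 1"):
            ContextMask("empty", np.zeros(5, dtype=bool))


class TestBootstrapNull:
    def _toy(self, seed=0, genes=10, lines=40):
        fm, _ = make_null_dataset(lines, genes, seed=seed, mask_size=8)
        return quantile_normalize(fm)

    def test_identical_columns_give_all_tied_counters(self):
        col = np.random.default_rng(0).normal(size=5)
        fm = _fm(np.tile(col[:, None], 12), normalized=True)
        obs = np.zeros((5, 5))
        null = bootstrap_null(fm, 3, obs, B=1, seed=0)
        assert (null.count_ge == 1).all() and (null.count_le == 1).all()

    def test_fixed_seed_reproducible(self):
        fm = self._toy()
        obs = np.zeros((10, 10))
        a = bootstrap_null(fm, 8, obs, B=50, seed=123)
        b = bootstrap_null(fm, 8, obs, B=50, seed=123)
        np.testing.assert_array_equal(a.count_ge, b.count_ge)
        np.testing.assert_array_equal(a.count_le, b.count_le)

    def test_streaming_counters_equal_store_everything_oracle(self):
        fm = self._toy(seed=2)
        X = fm.values.to_numpy()
        mask = np.zeros(40, dtype=bool)
        mask[:8] = True
        res = dpcc_for_context(fm, ContextMask("ctx", mask))
        B = 200
        null = bootstrap_null(fm, 8, res.dpcc, B=B, seed=77)
        # oracle: store every replicate matrix, then count
        rng = np.random.default_rng(77)
        stored = []
        pcc_all = np.corrcoef(X)
        for _ in range(B):
            removed = rng.choice(40, size=8, replace=False)
            keep = np.ones(40, dtype=bool)
            keep[removed] = False
            stored.append(pcc_all - np.corrcoef(X[:, keep]))
        stored = np.array(stored)
        np.testing.assert_array_equal(null.count_ge, (stored >= res.dpcc).sum(axis=0))
        np.testing.assert_array_equal(null.count_le, (stored <= res.dpcc).sum(axis=0))

    def test_pair_subset_matches_full_matrix_counters(self):
        fm = self._toy(seed=3)
        mask = np.zeros(40, dtype=bool)
        mask[5:13] = True
        res = dpcc_for_context(fm, ContextMask("ctx", mask))
        pairs = np.array([[0, 1], [2, 7], [3, 9]])
        full = bootstrap_null(fm, 8, res.dpcc, B=100, seed=5)
        sub = bootstrap_null(fm, 8, res.dpcc[pairs[:, 0], pairs[:, 1]], B=100, seed=5, pairs=pairs)
        np.testing.assert_array_equal(sub.count_ge, full.count_ge[pairs[:, 0], pairs[:, 1]])
        np.testing.assert_array_equal(sub.count_le, full.count_le[pairs[:, 0], pairs[:, 1]])

    def test_removing_too_many_lines_is_error(self):
        fm = self._toy()
        with pytest.raises(ValueError, match="remove"):
            bootstrap_null(fm, 38, np.zeros((10, 10)), B=1, seed=0)


class TestEmpiricalPvalues:
    def _null(self, ge, le, B):
        return BootstrapNull(
            "ctx", B, 0, 5, ("G0",), np.array([ge]), np.array([le]), pairs=np.array([[0, 0]])
        )

    def test_direct_formula_evaluation(self):
        assert empirical_pvalues(self._null(25, 180, 200))[0] == pytest.approx(0.25)

    def test_floor_at_one_over_B(self):
        assert empirical_pvalues(self._null(0, 1000, 1000))[0] == pytest.approx(0.001)

    def test_null_median_gives_p_one(self):
        assert empirical_pvalues(self._null(100, 100, 200))[0] == 1.0

    def test_values_are_multiples_of_resolution(self):
        fm = quantile_normalize(make_null_dataset(30, 12, seed=4, mask_size=6)[0])
        mask = np.zeros(30, dtype=bool)
        mask[:6] = True
        res = dpcc_for_context(fm, ContextMask("ctx", mask))
        null = bootstrap_null(fm, 6, res.dpcc, B=40, seed=1)
        p = empirical_pvalues(null)
        np.testing.assert_allclose(np.round(p * 40), p * 40, atol=1e-9)
        assert (p >= 1 / 40).all() and (p <= 1.0).all()


class TestClassifyEdges:
    def _result(self):
        genes = tuple(f"G{i}" for i in range(4))
        from contextnet.diffnet import CorrelationMatrix

        pcc_all = np.eye(4)
        pcc_excl = np.eye(4)
        dpcc = np.zeros((4, 4))
        dpcc[0, 1] = dpcc[1, 0] = 0.3
        dpcc[2, 3] = dpcc[3, 2] = -0.2
        dpcc[0, 2] = dpcc[2, 0] = 0.5  # will get a large p
        mask = ContextMask("ctx", np.array([True] * 3 + [False] * 7))
        return DpccResult(
            mask,
            CorrelationMatrix(genes, pcc_all, "all"),
            CorrelationMatrix(genes, pcc_excl, "excluding:ctx"),
            dpcc,
        )

    def test_sign_maps_to_goi_loi_and_alpha_filters(self):
        res = self._result()
        p = np.ones((4, 4))
        p[0, 1] = p[1, 0] = 0.001
        p[2, 3] = p[3, 2] = 0.001
        p[0, 2] = p[2, 0] = 0.05
        et = classify_edges(res, p, alpha=0.001)
        df = et.edges.set_index(["geneA", "geneB"])
        assert df.loc[("G0", "G1"), "class"] == "GOI"
        assert df.loc[("G2", "G3"), "class"] == "LOI"
        assert ("G0", "G2") not in df.index  # p 0.05 > alpha

    def test_min_abs_dpcc_filter_and_enumeration_oracle(self):
        res = self._result()
        p = np.full((4, 4), 0.001)
        et = classify_edges(res, p, alpha=0.001, min_abs_dpcc=0.25)
        # oracle: exhaustive filter over the upper triangle
        expected = {
            (f"G{i}", f"G{j}")
            for i in range(4)
            for j in range(i + 1, 4)
            if abs(res.dpcc[i, j]) >= 0.25 and res.dpcc[i, j] != 0
        }
        assert set(map(tuple, et.edges[["geneA", "geneB"]].to_numpy())) == expected

    def test_no_self_pairs_and_canonical_order(self):
        res = self._result()
        et = classify_edges(res, np.full((4, 4), 0.001), alpha=0.001)
        assert (et.edges["geneA"] < et.edges["geneB"]).all()


class TestSummarizeAndModel:
    def test_summary_additive_over_contexts(self):
        fm, _ = make_null_dataset(40, 12, seed=11, mask_size=8)
        masks = {f"c{k}": np.roll(np.arange(40) < 8, 5 * k) for k in range(3)}
        model = DifferentialNetwork(fm, masks)
        out = model.fit(B=30, seed=2, alpha=1.0)  # alpha 1: keep every pair as an edge
        per_context = [len(et) for et in out.edges.values()]
        total_row = out.summary_table().iloc[-1]
        assert total_row["feature"] == "TOTAL"
        assert total_row["n_goi"] + total_row["n_loi"] == sum(per_context)

    def test_empty_edge_tables_summarize_to_zero(self):
        df = summarize_features([])
        assert df.iloc[-1]["n_goi"] == 0 and df.iloc[-1]["n_loi"] == 0

    def test_model_fit_deterministic_for_seed(self):
        fm, masks = make_null_dataset(40, 10, seed=13, mask_size=8)
        out1 = DifferentialNetwork(fm, masks).fit(B=25, seed=3)
        out2 = DifferentialNetwork(fm, masks).fit(B=25, seed=3)
        pd.testing.assert_frame_equal(out1.edge_table().edges, out2.edge_table().edges)

    def test_null_pvalues_approximately_uniform(self):
        # no planted effect: empirical p over gene-disjoint pairs should be uniform
        fm, masks = make_null_dataset(80, 60, seed=21, mask_size=16)
        qn = quantile_normalize(fm)
        mask = masks["null_context_0"]
        res = dpcc_for_context(qn, ContextMask("null", mask))
        pairs = np.sort(np.random.default_rng(5).permutation(60).reshape(30, 2), axis=1)
        obs = res.dpcc[pairs[:, 0], pairs[:, 1]]
        null = bootstrap_null(qn, 16, obs, B=200, seed=6, pairs=pairs)
        p = empirical_pvalues(null)
        frac = (p <= 0.05).mean()
        margin = 2.576 * np.sqrt(0.05 * 0.95 / len(p))
        assert frac <= 0.05 + margin
        assert p.mean() == pytest.approx(0.5, abs=0.2)
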