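"""Friedman/BH machinery, PCA and consensus PCA, selection and trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from berrymet import stats as bst


class TestFriedman:
    def test_worked_example_rank_sums_and_statistic(self):
        # ranks per block -> rank sums (5, 8, 11); Q = 4.5, df = 2
        table = [[1, 2, 3], [2, 1, 3], [1, 2, 3], [1, 3, 2]]
        q, df, p = bst.friedman_from_table(table)
        assert q == pytest.approx(4.5)
        assert df == 2
        assert p == pytest.approx(sps.chi2.sf(4.5, 2))
        assert p == pytest.approx(0.105, abs=1e-3)

    def test_identical_orderings_reach_the_design_maximum(self):
        table = [[1, 2, 3]] * 4  # rank sums (4, 8, 12)
        q, df, p = bst.friedman_from_table(table)
        assert q == pytest.approx(8.0)

    def test_constant_data_is_null(self):
        q, df, p = bst.friedman_from_table(np.ones((4, 3)))
        assert q == 0.0 and p == 1.0

    def test_agrees_with_scipy_on_untied_data(self):
        rng = np.random.default_rng(0)
        table = rng.normal(size=(8, 4))
        q, df, p = bst.friedman_from_table(table)
        q_ref, p_ref = sps.friedmanchisquare(*table.T)
        assert q == pytest.approx(q_ref)
        assert p == pytest.approx(p_ref)

    def test_tie_correction_matches_scipy(self):
        table = np.array([[1.0, 1.0, 2.0], [2.0, 1.0, 1.0], [1.0, 2.0, 2.0], [3.0, 1.0, 2.0]])
        q, _, p = bst.friedman_from_table(table)
        q_ref, p_ref = sps.friedmanchisquare(*table.T)
        assert q == pytest.approx(q_ref)

    def test_long_form_requires_complete_single_valued_cells(self):
        with pytest.raises(ValueError, match="cells"):
            bst.friedman_test([1, 2, 3], ["a", "a", "b"], [1, 1, 1])
        q, df, p = bst.friedman_test(
            [1, 2, 3, 2, 1, 3],
            ["a", "b", "c", "a", "b", "c"],
            [1, 1, 1, 2, 2, 2],
        )
        assert df == 2

    def test_null_p_values_are_super_uniform_in_the_rejection_tail(self):
        # rank-based p-values are discrete and the chi-square approximation
        # is only trustworthy in the tail that drives FDR decisions;
        # validity there means P(p <= t) <= t up to Monte-Carlo error
        rng = np.random.default_rng(42)
        pvals = np.array(
            [bst.friedman_from_table(rng.normal(size=(4, 4)))[2] for _ in range(500)]
        )
        for t in np.unique(pvals[pvals <= 0.1]):
            frac = (pvals <= t).mean()
            se = np.sqrt(t * (1 - t) / 500)
            assert frac <= t + 3 * se + 1e-9


class TestBenjaminiHochberg:
    def test_step_up_recursion_worked_example(self):
        q, reject = bst.bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])
        assert reject.tolist() == [True, True, True, False]

    def test_equal_p_values_are_unchanged(self):
        q, _ = bst.bh_fdr([0.2, 0.2, 0.2])
        np.testing.assert_allclose(q, [0.2, 0.2, 0.2])

    def test_single_test_passes_through(self):
        q, _ = bst.bh_fdr([0.031])
        assert q[0] == pytest.approx(0.031)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        q, _ = bst.bh_fdr(pvals)
        _, q_ref, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bst.bh_fdr([0.2, 1.4])


class TestPca:
    def test_two_uncorrelated_equal_variance_variables_split_tev(self):
        X = pd.DataFrame([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        model = bst.PeakRatioPCA(n_components=2, scaling="none").fit(X)
        np.testing.assert_allclose(model.tev_.to_numpy(), [50.0, 50.0])

    def test_rank_one_matrix_is_fully_explained_by_pc1(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([0.5, -1.0, 2.0])
        X = pd.DataFrame(np.outer(u, v))
        model = bst.PeakRatioPCA(n_components=2, scaling="none").fit(X)
        assert model.tev_["PC1"] == pytest.approx(100.0)

    def test_full_rank_reconstruction_of_scaled_matrix(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        model = bst.PeakRatioPCA(n_components=6).fit(X)
        Xs = (X - model.means_) / model.scales_
        approx = model.scores_.to_numpy() @ model.loadings_.to_numpy().T
        # 10 samples give at most 9 informative components; use what exists
        k = model.scores_.shape[1]
        u, s, vt = np.linalg.svd(Xs.to_numpy(), full_matrices=False)
        np.testing.assert_allclose(
            approx, (u[:, :k] * s[:k]) @ vt[:k], atol=1e-8
        )

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(12, 5)))
        l1 = bst.PeakRatioPCA(n_components=3).fit(X).loadings_
        l2 = bst.PeakRatioPCA(n_components=3).fit(-1 * X + X.mean() * 2).loadings_
        for c in l1.columns:
            idx = l1[c].abs().idxmax()
            assert l1.loc[idx, c] > 0

    def test_zero_variance_column_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5], "c": [2.0, 1, 4, 3]})
        with pytest.warns(UserWarning, match="zero-variance"):
            model = bst.PeakRatioPCA(n_components=2).fit(X)
        assert model.dropped_features_ == ["b"]

    def test_incomplete_matrix_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="complete"):
            bst.PeakRatioPCA().fit(X)


class TestHierarchicalPca:
    def test_single_block_equals_conventional_pca_up_to_sign(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(15, 7)))
        h = bst.HierarchicalPCA(n_components=3).fit(X, pd.Series(["b"] * 15, index=X.index))
        p = bst.PeakRatioPCA(n_components=3).fit(X)
        for c in ["PC1", "PC2", "PC3"]:
            cos = abs(h.super_loadings_[c] @ p.loadings_[c])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_two_identical_blocks_share_scores_and_loadings(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(10, 6))
        X = pd.DataFrame(np.vstack([A, A]), index=[f"s{i}" for i in range(20)])
        blocks = pd.Series(["a"] * 10 + ["b"] * 10, index=X.index)
        h = bst.HierarchicalPCA(n_components=2).fit(X, blocks)
        np.testing.assert_allclose(
            h.block_scores_["a"].to_numpy(), h.block_scores_["b"].to_numpy(), atol=1e-8
        )
        single = bst.HierarchicalPCA(n_components=2).fit(
            pd.DataFrame(A), pd.Series(["a"] * 10)
        )
        for c in ["PC1", "PC2"]:
            cos = abs(h.super_loadings_[c] @ single.super_loadings_[c])
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_planted_shared_block_pattern_tops_the_super_loadings(self):
        rng = np.random.default_rng(5)
        pattern = np.array([1, -1] * 6, float) * 2.0
        X = rng.normal(size=(36, 40))
        for b in range(3):
            X[b * 12 : (b + 1) * 12, :4] += pattern[:, None]
        X = pd.DataFrame(X)
        blocks = pd.Series(np.repeat(["t12", "t18", "t24"], 12), index=X.index)
        h = bst.HierarchicalPCA(n_components=1).fit(X, blocks)
        top4 = set(h.super_loadings_["PC1"].abs().nlargest(4).index)
        assert top4 == {0, 1, 2, 3}

    def test_unlabelled_sample_rejected(self):
        X = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError, match="block"):
            bst.HierarchicalPCA().fit(X, pd.Series({0: "a", 1: "a"}))


class TestSelectionAndTrends:
    def _meta(self):
        rows = []
        for t in ("12", "18", "24"):
            for d in ("LD", "SD", "SD+NI"):
                for b in "1234":
                    rows.append((f"S{t}_{d}_{b}", "biological", t, d, b))
        for b in "1234":
            rows.append((f"Samb_LD_{b}", "biological", "ambient", "LD", b))
        return pd.DataFrame(
            rows, columns=["sample_id", "type", "temperature", "daylength", "block"]
        ).assign(polarity="negative", injection_order=0)

    def _matrix(self, seed=0, n_null=30):
        meta = self._meta()
        rng = np.random.default_rng(seed)
        temps = meta.set_index("sample_id")["temperature"]
        X = pd.DataFrame(
            rng.lognormal(0, 0.1, size=(len(meta), n_null + 2)),
            index=meta["sample_id"],
        )
        fold = temps.map({"12": 1.0, "18": 1.5, "24": 2.25, "ambient": 1.0})
        X[0] = X[0] * fold  # planted temperature-increasing feature
        X[1] = X[1] * temps.map(
            {"12": 1.0, "18": 1.0, "24": 1.0, "ambient": 3.0}
        )  # planted ambient-elevated feature
        return X, meta

    def test_friedman_selector_flags_planted_temperature_feature(self):
        # with 4 replicate blocks the smallest attainable Friedman p is
        # ~0.0074, so assert ordering/p rather than a q cut that the
        # design's rank granularity cannot reach at this feature count
        X, meta = self._matrix()
        sel = bst.FriedmanSelector("temperature").fit(X, meta)
        assert sel.results_.loc[0, "p"] <= 0.015
        assert sel.results_.loc[0, "p"] == sel.results_["p"].min()
        assert sel.results_["p"].loc[2:].min() > sel.results_.loc[0, "p"]
        assert (sel.results_["q"] >= sel.results_["p"] - 1e-12).all()

    def test_ambient_excluded_design_has_three_treatments(self):
        X, meta = self._matrix()
        sel = bst.FriedmanSelector("temperature", include_ambient=False).fit(X, meta)
        assert sel.treatments_ == ["12", "18", "24"]
        assert sel.results_.loc[0, "p"] <= 0.02  # k=3, n=4 floor is 0.0183

    def test_daylength_design_blocks_are_temperature_by_replicate(self):
        X, meta = self._matrix()
        cells, blocks, treatments = bst.friedman_cells(X, meta, "daylength")
        assert cells.shape[:2] == (12, 3)
        assert treatments == ["LD", "SD", "SD+NI"]

    def test_trend_classification_examples(self):
        means = pd.DataFrame(
            {
                "12": [0.0062, 1.0, 1.0, 1.0],
                "18": [0.0048, 2.0, 1.1, 1.0],
                "24": [0.0046, 3.0, 0.9, 1.0],
                "ambient": [0.006, 1.0, 1.0, 2.0],
            },
            index=["asc", "up", "peak", "amb"],
        )
        classes = bst.classify_trends(means)
        assert classes["asc"] == "temp-down"
        assert classes["up"] == "temp-up"
        assert classes["peak"] == "none"
        assert classes["amb"] == "ambient-up"

    def test_unselected_features_are_never_classified(self):
        means = pd.DataFrame({"12": [1.0], "18": [2.0], "24": [3.0], "ambient": [1.0]})
        selected = pd.Series([False])
        assert bst.classify_trends(means, selected=selected).iloc[0] == "none"

    def test_selection_requires_both_significance_and_prominence(self):
        results = pd.DataFrame({"q": [0.001, 0.001, 0.9]}, index=list("abc"))
        loadings = pd.DataFrame({"PC1": [0.9, 0.01, 0.95]}, index=list("abc"))
        sel = bst.select_significant(results, loadings, ["PC1"], prominence_pct=50)
        assert sel.tolist() == [True, False, False]


class TestMethodCorrelation:
    def test_identical_and_inverted_vectors(self):
        r, _ = bst.correlate_methods([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)
        r, _ = bst.correlate_methods([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        r, p = bst.correlate_methods([1, 2, 3], [2, 4, 7])
        assert r == pytest.approx(0.99340, abs=1e-5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bst.correlate_methods([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            bst.correlate_methods([1, 2], [1, 2])
        with pytest.raises(ValueError):
            bst.correlate_methods([1, np.nan, 2], [1, 2, 3])
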