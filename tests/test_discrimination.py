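import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import oracles as orc
import paradiomics as pr
from paradiomics import discrimination as disc


class TestVolumeCorrection:
    def test_exact_power_law_becomes_constant(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(100, 900, size=60)
        X = pd.DataFrame({"f": 3.0 * V**1.5})
        Xc, report = disc.correct_volume_dependency(X, V)
        assert report.loc["f", "corrected"]
        assert report.loc["f", "b"] == pytest.approx(1.5, abs=1e-8)
        np.testing.assert_allclose(Xc["f"], Xc["f"].iloc[0], atol=1e-8)

    def test_volume_independent_feature_passes_through(self):
        rng = np.random.default_rng(1)
        V = rng.uniform(100, 900, size=60)
        X = pd.DataFrame({"f": rng.normal(size=60)})
        Xc, report = disc.correct_volume_dependency(X, V)
        assert not report.loc["f", "corrected"]
        np.testing.assert_array_equal(Xc["f"], X["f"])

    def test_shift_invariance_of_passthrough(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(100, 900, size=60)
        y = rng.normal(size=60)
        X1, _ = disc.correct_volume_dependency(pd.DataFrame({"f": y}), V)
        X2, _ = disc.correct_volume_dependency(pd.DataFrame({"f": y + 5.0}), V)
        np.testing.assert_allclose(X2["f"] - X1["f"], 5.0, atol=1e-12)

    def test_non_positive_volumes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            disc.correct_volume_dependency(pd.DataFrame({"f": [1.0, 2.0]}), [0.0, 5.0])

    def test_corrected_feature_loses_volume_dependence(self):
        rng = np.random.default_rng(3)
        V = rng.uniform(100, 900, size=200)
        X = pd.DataFrame({"f": 2.0 * V**0.8 * np.exp(0.05 * rng.normal(size=200))})
        Xc, _ = disc.correct_volume_dependency(X, V)
        rho, _ = stats.spearmanr(Xc["f"], V)
        assert abs(rho) < 0.15


class TestKruskalWallis:
    def test_textbook_two_group_example(self):
        h, df, p, deg = pr.kruskal_wallis_h(
            np.array([1, 2, 3, 4, 5, 6.0]), np.array(["a"] * 3 + ["b"] * 3)
        )
        assert h == pytest.approx(27 / 7)
        assert df == 1 and not deg

    def test_identical_rank_distributions_give_zero(self):
        h, _, p, _ = pr.kruskal_wallis_h(
            np.array([1, 2, 1, 2.0]), np.array(["a", "a", "b", "b"])
        )
        assert h == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_midrank_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 5, size=30).astype(float)  # heavy ties
        groups = rng.choice(["a", "b", "c"], size=30)
        if len(set(groups)) < 2:
            pytest.skip("degenerate draw")
        h, _, _, _ = pr.kruskal_wallis_h(values, groups)
        assert h == pytest.approx(orc.kruskal_oracle(values, list(groups)), abs=1e-10)

    def test_constant_values_flagged_degenerate(self):
        h, _, p, deg = pr.kruskal_wallis_h(np.ones(10), np.array(["a"] * 5 + ["b"] * 5))
        assert deg and p == 1.0


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        p = pd.Series({"f1": 0.01, "f2": 0.02, "f3": 0.2, "f4": 0.8})
        d = pr.benjamini_hochberg(p, q=0.25)
        np.testing.assert_allclose(d["critical"], [0.0625, 0.125, 0.1875, 0.25])
        assert list(d[d["reject"]].index) == ["f1", "f2"]

    def test_all_ones_reject_nothing(self):
        d = pr.benjamini_hochberg(pd.Series({"a": 1.0, "b": 1.0}), q=0.25)
        assert not d["reject"].any()

    def test_agrees_with_statsmodels_step_up(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = pd.Series(rng.uniform(size=40), index=[f"f{i}" for i in range(40)])
        d = pr.benjamini_hochberg(p, q=0.25)
        reject, *_ = multipletests(p.to_numpy(), alpha=0.25, method="fdr_bh")
        assert set(d[d["reject"]].index) == set(p.index[reject])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_rejection_set_is_prefix_of_sorted_pvalues(self, ps):
        p = pd.Series(ps, index=[f"f{i}" for i in range(len(ps))])
        d = pr.benjamini_hochberg(p, q=0.25)
        rej = d["reject"].to_numpy()
        # d is sorted by (p, name); rejections must form a prefix
        assert not np.any(~rej[:-1] & rej[1:])


class TestRepeatedMeasuresCorrelation:
    def test_perfect_within_subject_slope(self):
        x = np.tile(np.arange(5.0), 3)
        subj = np.repeat(["s1", "s2", "s3"], 5)
        y = 2.0 * x + np.repeat([0.0, 10.0, -5.0], 5)
        r, df, p, ok = pr.repeated_measures_correlation(x, y, subj)
        assert ok and r == pytest.approx(1.0)
        assert df == 15 - 3 - 1
        y2 = -x + np.repeat([0.0, 10.0, -5.0], 5)
        r2, *_ = pr.repeated_measures_correlation(x, y2, subj)
        assert r2 == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_centred_covariance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=24)
        y = rng.normal(size=24)
        subj = np.repeat([f"s{i}" for i in range(6)], 4)
        r, _, _, ok = pr.repeated_measures_correlation(x, y, subj)
        assert ok
        assert r == pytest.approx(orc.rmcorr_oracle(x, y, subj), abs=1e-12)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        n, k = 36, 6
        subj = np.repeat([f"s{i}" for i in range(k)], n // k)
        x = rng.normal(size=n) + np.repeat(rng.normal(size=k), n // k)
        y = 0.5 * x + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "subject": subj})
        res = pingouin.rm_corr(data=df, x="x", y="y", subject="subject")
        r, dof, p, ok = pr.repeated_measures_correlation(x, y, subj)
        assert r == pytest.approx(float(res["r"].iloc[0]), abs=1e-6)
        assert dof == int(res["dof"].iloc[0])
        assert p == pytest.approx(float(res["pval"].iloc[0]), rel=1e-4)

    def test_zero_within_subject_variance_flagged(self):
        x = np.repeat([1.0, 2.0], 4)
        y = np.arange(8.0)
        subj = np.repeat(["a", "b"], 4)
        *_, ok = pr.repeated_measures_correlation(x, y, subj)
        assert not ok

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        subj = np.repeat([f"s{i}" for i in range(6)], 5)
        R = pr.rmcorr_matrix(X, subj)
        np.testing.assert_allclose(R.to_numpy(), R.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(R), 1.0)
        assert R.to_numpy().min() >= -1 - 1e-12 and R.to_numpy().max() <= 1 + 1e-12


class TestSingleFeatureScores:
    def test_perfectly_separating_feature_scores_one(self):
        n = 40
        labels = np.array(["basal"] * (n // 2) + ["luminal"] * (n // 2))
        X = pd.DataFrame({"f": np.r_[np.zeros(n // 2), np.ones(n // 2)]})
        ids = np.array([f"s{i}" for i in range(n)])
        s = pr.single_feature_scores(X, labels, ids, seed=0)
        assert s["f"] == pytest.approx(1.0)

    def test_noise_feature_scores_near_chance(self):
        means = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            labels = np.array(["basal", "luminal"] * (n // 2))
            X = pd.DataFrame({"f": rng.normal(size=n)})
            ids = np.array([f"s{i}" for i in range(n)])
            means.append(pr.single_feature_scores(X, labels, ids, seed=seed)["f"])
        assert np.mean(means) == pytest.approx(0.5, abs=0.1)

    def test_duplicated_features_score_identically(self):
        rng = np.random.default_rng(3)
        n = 60
        labels = np.array(["basal", "luminal"] * (n // 2))
        col = rng.normal(size=n) + (labels == "basal") * 0.8
        X = pd.DataFrame({"f1": col, "f2": col})
        ids = np.array([f"s{i % 12}" for i in range(n)])
        s = pr.single_feature_scores(X, labels, ids, seed=9)
        assert s["f1"] == s["f2"]

    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two classes"):
            pr.single_feature_scores(X, np.array(["a", "a"]), np.array(["s1", "s2"]))


class TestPruneCorrelated:
    def _matrix(self, names, pairs):
        R = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for a, b, r in pairs:
            R.loc[a, b] = R.loc[b, a] = r
        return R

    def test_identical_pair_keeps_higher_scorer(self):
        R = self._matrix(["a", "b"], [("a", "b", 1.0)])
        rep = pr.prune_correlated(["a", "b"], R, pd.Series({"a": 0.6, "b": 0.9}))
        assert rep.selected == ["b"]
        assert rep.pruned_pairs[0]["dropped"] == "a"

    def test_tie_broken_by_registry_order(self):
        R = self._matrix(["a", "b"], [("a", "b", 0.95)])
        rep = pr.prune_correlated(["a", "b"], R, pd.Series({"a": 0.7, "b": 0.7}))
        assert rep.selected == ["a"]

    def test_correlated_chain_keeps_best_only(self):
        R = self._matrix(
            ["a", "b", "c"],
            [("a", "b", 0.95), ("b", "c", 0.93), ("a", "c", 0.92)],
        )
        rep = pr.prune_correlated(
            ["a", "b", "c"], R, pd.Series({"a": 0.9, "b": 0.8, "c": 0.7})
        )
        assert rep.selected == ["a"]

    def test_no_pair_above_threshold_is_identity(self):
        R = self._matrix(["a", "b"], [("a", "b", 0.5)])
        rep = pr.prune_correlated(["a", "b"], R, pd.Series({"a": 0.6, "b": 0.9}))
        assert rep.selected == ["a", "b"]

    def test_no_surviving_pair_exceeds_threshold(self):
        rng = np.random.default_rng(0)
        names = [f"f{i}" for i in range(8)]
        M = rng.uniform(-1, 1, size=(8, 8))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        R = pd.DataFrame(M, index=names, columns=names)
        scores = pd.Series(rng.uniform(size=8), index=names)
        rep = pr.prune_correlated(names, R, scores, threshold=0.5)
        for i, a in enumerate(rep.selected):
            for b in rep.selected[i + 1:]:
                assert abs(R.loc[a, b]) <= 0.5


class TestShapley:
    def _toy_model(self, seed=0, n=12, k=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, k))
        w = np.arange(1, k + 1, dtype=float)
        labels = np.where(X @ w + 0.3 * rng.normal(size=n) > 0, "luminal", "basal")
        return X, labels

    def test_linear_model_exact_attributions(self):
        # for f(x) = w.x the interventional Shapley value is w_i (x_i - bg_i)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        bg = rng.normal(size=(10, 4))
        w = np.array([1.0, -2.0, 0.5, 3.0])
        phi, base = pr.shapley_attributions(lambda A: A @ w, X, bg, seed=0)
        expected = w * (X - bg.mean(axis=0))
        np.testing.assert_allclose(phi, expected, atol=1e-10)
        assert base == pytest.approx(bg.mean(axis=0) @ w)

    def test_permutation_estimator_matches_linear_closed_form(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 6))
        bg = rng.normal(size=(8, 6))
        w = rng.normal(size=6)
        phi, base = pr.shapley_attributions(
            lambda A: A @ w, X, bg, seed=3, exact_max_features=0, n_permutations=50
        )
        # linear models have no interactions: every permutation yields the
        # same telescoping, so even the MC estimator is exact
        np.testing.assert_allclose(phi, w * (X - bg.mean(axis=0)), atol=1e-10)

    def test_forest_attributions_match_coalition_oracle(self):
        from sklearn.ensemble import RandomForestClassifier

        X, labels = self._toy_model()
        forest = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, labels)
        idx = int(np.nonzero(forest.classes_ == "luminal")[0][0])
        predict = lambda A: forest.predict_proba(A)[:, idx]
        bg = X[:8]
        phi, base = pr.shapley_attributions(predict, X, bg, seed=0)
        for i in range(len(X)):
            expected = orc.shapley_oracle(predict, X[i], bg)
            np.testing.assert_allclose(phi[i], expected, atol=1e-6)

    @pytest.mark.parametrize("exact_max", [15, 0])  # exact and MC paths
    def test_local_accuracy_on_every_sample(self, exact_max):
        from sklearn.ensemble import RandomForestClassifier

        X, labels = self._toy_model(seed=4, n=16)
        forest = RandomForestClassifier(n_estimators=30, random_state=1).fit(X, labels)
        idx = int(np.nonzero(forest.classes_ == "luminal")[0][0])
        predict = lambda A: forest.predict_proba(A)[:, idx]
        phi, base = pr.shapley_attributions(
            predict, X, X[:10], seed=5, exact_max_features=exact_max, n_permutations=8
        )
        np.testing.assert_allclose(base + phi.sum(axis=1), predict(X), atol=1e-8)

    def test_fit_forest_ranking_single_strong_feature_on_top(self):
        rng = np.random.default_rng(6)
        n = 60
        labels = np.array(["basal", "luminal"] * (n // 2))
        X = pd.DataFrame({
            "signal": (labels == "luminal") * 2.0 + 0.3 * rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        ranking = pr.fit_forest_and_shapley(X, labels, seed=0)
        assert ranking.mean_abs.index[0] == "signal"
        np.testing.assert_allclose(
            ranking.base_value + ranking.attributions.sum(axis=1),
            ranking.model_output, atol=1e-8,
        )

    def test_single_feature_input_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            pr.fit_forest_and_shapley(
                pd.DataFrame({"f": [1.0, 2.0]}), np.array(["a", "b"])
            )
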