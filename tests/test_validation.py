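"""Accuracy measures, estimator baselines, LOO, resection analyses."""

import numpy as np
import pandas as pd
import pytest

import seizprop as sp


def _obs(region_ids, status, onsets):
    return sp.SeizureObservation(
        list(region_ids), np.array(status, dtype=object), np.asarray(onsets, float)
    )


class TestStatePredictionAccuracy:
    def test_all_draws_correct(self):
        assert sp.state_prediction_accuracy([10.0, 50.0, 80.0], True) == 1.0

    def test_half_split_for_nonseizing_truth(self):
        draws = [80.0, 85.0, 95.0, 100.0]
        assert sp.state_prediction_accuracy(draws, False, t_lim=90.0) == 0.5

    def test_complementarity(self):
        rng = np.random.default_rng(0)
        draws = rng.uniform(50, 130, 200)
        a = sp.state_prediction_accuracy(draws, True)
        b = sp.state_prediction_accuracy(draws, False)
        assert np.isclose(a + b, 1.0)


class TestOnsetPredictionAccuracy:
    def test_exact_draws(self):
        assert sp.onset_prediction_accuracy([30.0, 30.0], 30.0) == 1.0

    def test_partial_window(self):
        assert np.isclose(
            sp.onset_prediction_accuracy([30.0, 34.0, 40.0], 30.0, T=5.0), 2 / 3
        )

    def test_border_region_excluded(self):
        assert sp.onset_prediction_accuracy([80.0], 86.0, T=5.0, t_lim=90.0) is None


class TestEstimates:
    def _three_region_obs(self):
        # region 0 is the target; others observed at 40, 50, inf
        return _obs(
            ["t", "a", "b", "c"],
            ["seizing", "seizing", "seizing", "non-seizing"],
            [42.0, 40.0, 50.0, np.inf],
        )

    def test_unweighted_all_others_seizing(self):
        obs = _obs(["t", "a", "b"], ["seizing"] * 3, [30.0, 40.0, 50.0])
        state, _ = sp.unweighted_estimate(obs, 0, True)
        assert state == 1.0

    def test_unweighted_state_count(self):
        state, _ = sp.unweighted_estimate(self._three_region_obs(), 0, True)
        assert np.isclose(state, 2 / 3)

    def test_unweighted_onset_count(self):
        _, onset = sp.unweighted_estimate(self._three_region_obs(), 0, True, 42.0)
        assert np.isclose(onset, 1 / 3)  # only 40 is within 5 s of 42

    def test_weighted_equals_unweighted_under_uniform_weights(self):
        obs = self._three_region_obs()
        W = sp.Connectome(np.full((4, 4), 0.2) - 0.2 * np.eye(4), list(obs.region_ids))
        su, ou = sp.unweighted_estimate(obs, 0, True, 42.0)
        sw, ow = sp.weighted_estimate(obs, W, 0, True, 42.0)
        assert np.isclose(su, sw) and np.isclose(ou, ow)

    def test_weighted_degenerate_weight_ignores_other_regions(self):
        obs = _obs(
            ["t", "a", "b"], ["seizing", "seizing", "non-seizing"], [42.0, 40.0, np.inf]
        )
        W = np.zeros((3, 3))
        W[0, 1] = 0.9  # only region a is connected to the target
        con = sp.Connectome(W, ["t", "a", "b"])
        state, _ = sp.weighted_estimate(obs, con, 0, True)
        assert state == 1.0

    def test_weighted_scale_invariance(self):
        obs = self._three_region_obs()
        rng = np.random.default_rng(1)
        M = rng.uniform(0, 0.2, (4, 4))
        np.fill_diagonal(M, 0.0)
        a = sp.weighted_estimate(obs, sp.Connectome(M, list(obs.region_ids)), 0, True, 42.0)
        b = sp.weighted_estimate(obs, sp.Connectome(M / 3, list(obs.region_ids)), 0, True, 42.0)
        assert np.allclose(a, b)

    def test_weighted_zero_total_weight_undefined(self):
        obs = _obs(["t", "a"], ["seizing", "seizing"], [42.0, 40.0])
        con = sp.Connectome(np.zeros((2, 2)), ["t", "a"])
        assert sp.weighted_estimate(obs, con, 0, True) == (None, None)


@pytest.fixture(scope="module")
def hub_seizure():
    """Region 1's onset is forced by a dominant afferent from region 0;
    most observed regions are non-seizing."""
    n = 8
    W = np.zeros((n, n))
    W[1, 0] = 1.0  # dominant drive 0 -> 1
    con = sp.Connectome(W, [f"r{i}" for i in range(n)])
    # rates: autonomous seizure only for region 0; input pushes region 1
    q = sp.ExcitationParams(-6.0, 0.0, 3.2, 2.0)
    c = np.full(n, -1.0)  # cannot seize autonomously within t_lim
    c[0] = 3.0
    t = sp.simulate_onsets(con, q, c).t
    status = ["seizing" if ti < 90 else "non-seizing" for ti in t]
    onsets = np.where(t < 90, t, np.inf)
    return con, q, _obs(con.region_ids, status, onsets)


class TestRunLoo:
    def test_network_drive_beats_unweighted_estimate(self, hub_seizure):
        con, q, obs = hub_seizure
        assert obs.status[1] == "seizing"  # driven by region 0
        df = sp.run_loo(obs, con, q, seed=7, chains=2, warmup=300, draws=300)
        row = df[(df.region == "r1")].set_index("method")
        assert row.loc["inference", "state_pa"] > row.loc["unweighted", "state_pa"]

    def test_row_count_is_three_per_observed_region(self, hub_seizure):
        con, q, obs = hub_seizure
        df = sp.run_loo(obs, con, q, seed=8, chains=2, warmup=200, draws=200)
        assert len(df) == 3 * obs.n_obs

    def test_hiding_one_region_leaves_others_untouched(self, hub_seizure):
        _, _, obs = hub_seizure
        hidden = obs.hide_region(1)
        assert hidden.status[1] == "hidden" and np.isinf(hidden.onset_s[1])
        others = [i for i in range(obs.n_regions) if i != 1]
        assert np.array_equal(hidden.status[others], obs.status[others])
        assert np.array_equal(hidden.onset_s[others], obs.onset_s[others])


class TestPrecisionRecall:
    def test_perfect_match_point(self):
        p = np.array([0.9, 0.8, 0.1, 0.0])
        ids = ["a", "b", "c", "d"]
        df = sp.precision_recall_curve(p, ids, {"a", "b"}, thresholds=[0.5])
        assert df.precision[0] == 1.0 and df.recall[0] == 1.0

    def test_disjoint_prediction(self):
        p = np.array([0.9, 0.0, 0.0])
        df = sp.precision_recall_curve(p, ["a", "b", "c"], {"b"}, thresholds=[0.5])
        assert df.precision[0] == 0.0 and df.recall[0] == 0.0

    def test_counts(self):
        p = np.array([0.9, 0.1, 0.9, 0.0])
        df = sp.precision_recall_curve(p, ["A", "B", "C", "D"], {"A", "B"},
                                       thresholds=[0.5])
        assert df.precision[0] == 0.5 and df.recall[0] == 0.5
        assert df.tp[0] == 1 and df.fp[0] == 1 and df.fn[0] == 1

    def test_recall_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 30)
        ids = [f"r{i}" for i in range(30)]
        df = sp.precision_recall_curve(p, ids, set(ids[:5]), drop_empty=False)
        assert np.all(np.diff(df.recall.to_numpy()) <= 1e-12)

    def test_empty_prediction_flagged(self):
        df = sp.precision_recall_curve(
            np.zeros(3), ["a", "b", "c"], {"a"}, thresholds=[0.5], drop_empty=False
        )
        assert bool(df.no_predictions[0]) and df.precision[0] == 1.0


def _driver_scenario():
    """Single highly excitable driver (region 0) recruits everyone else; the
    rest cannot seize on their own."""
    n = 6
    W = np.zeros((n, n))
    W[1:, 0] = 1.0
    con = sp.Connectome(W, [f"r{i}" for i in range(n)])
    q = sp.ExcitationParams(-6.0, 0.0, 3.2, 2.0)
    c = np.full(n, -1.0)
    c[0] = 3.0
    return con, q, c


class TestVirtualResection:
    def test_no_resection_no_reduction(self):
        con, q, c = _driver_scenario()
        res = sp.virtual_resection(con, [], c[None, :], q)
        assert res.relative_reduction == 0.0
        assert res.n_preop == res.n_postop

    def test_resecting_the_driver_stops_the_seizure(self):
        con, q, c = _driver_scenario()
        res = sp.virtual_resection(con, ["r0"], c[None, :], q)
        assert res.n_preop == 6 and res.n_postop == 0
        assert res.relative_reduction == 1.0
        assert res.probability_decrease > 0.9

    def test_postop_count_excludes_resected_regions(self):
        con, q, c = _driver_scenario()
        res = sp.virtual_resection(con, ["r3"], c[None, :], q)
        assert res.n_postop <= 5

    def test_resecting_disconnected_region_changes_only_itself(self):
        con, q, c = _driver_scenario()
        # r5 receives drive but projects nowhere: removing it only removes it
        pre = sp.virtual_resection(con, [], c[None, :], q)
        post = sp.virtual_resection(con, ["r5"], c[None, :], q)
        assert pre.n_preop - post.n_postop == 1


class TestCompareOutcomeGroups:
    def test_separated_groups_give_small_p(self):
        red = {f"p{i}": (0.9 - 0.02 * i, "I") for i in range(6)}
        red.update({f"q{i}": (0.2 + 0.02 * i, "IV") for i in range(6)})
        out = sp.compare_outcome_groups(red)
        assert out["n_good"] == 6 and out["n_poor"] == 6
        assert out["U"] == 36.0 and out["p"] < 0.01  # complete separation

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            sp.compare_outcome_groups({"p0": (0.5, "I")})


class TestResectionScenario:
    def test_strict_half_cut(self):
        sc = sp.ResectionScenario.from_fractions(
            ["a", "b", "c"], [0.5, 0.51, 1.0], engel="II"
        )
        assert sc.resected == {"b", "c"} and sc.engel == "II"


class _IdentityModel:
    """Predicts the first feature; R^2 score."""

    def predict(self, X):
        return np.asarray(X)[:, 0].astype(float)

    def score(self, X, y):
        pred = self.predict(X)
        y = np.asarray(y, float)
        return 1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)


class TestPermutationFeatureImportance:
    def test_informative_feature_dominates(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 3))
        y = X[:, 0].copy()
        imp = sp.permutation_feature_importance(_IdentityModel(), X, y, K=30, seed=4)
        assert imp.iloc[0] > 0.5
        assert np.all(np.abs(imp.iloc[1:]) < 1e-12)  # unused features

    def test_independent_target_gives_null_importances(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((300, 3))
        y = rng.standard_normal(300)
        from sklearn.linear_model import LinearRegression

        model = LinearRegression().fit(X, y)
        imp = sp.permutation_feature_importance(model, X, y, K=30, seed=6)
        assert np.all(np.abs(imp.to_numpy()) < 0.1)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((150, 2)), columns=["u", "v"])
        y = X["u"] + 0.5 * X["v"]
        from sklearn.linear_model import LinearRegression

        model = LinearRegression().fit(X, y)
        imp1 = sp.permutation_feature_importance(model, X, y, K=20, seed=8)
        model2 = LinearRegression().fit(X[["v", "u"]], y)
        imp2 = sp.permutation_feature_importance(model2, X[["v", "u"]], y, K=20, seed=8)
        assert abs(imp1["u"] - imp2["u"]) < 0.05
        assert abs(imp1["v"] - imp2["v"]) < 0.05

    def test_matches_sklearn_reference(self):
        """Independent cross-check against scikit-learn's implementation."""
        from sklearn.inspection import permutation_importance
        from sklearn.linear_model import LinearRegression

        rng = np.random.default_rng(9)
        X = rng.standard_normal((250, 3))
        y = 2 * X[:, 0] - X[:, 1] + 0.1 * rng.standard_normal(250)
        model = LinearRegression().fit(X, y)
        ours = sp.permutation_feature_importance(model, X, y, K=50, seed=10)
        ref = permutation_importance(model, X, y, n_repeats=50, random_state=0)
        assert np.allclose(ours.to_numpy(), ref.importances_mean, atol=0.05)
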