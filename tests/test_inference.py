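"""Statistical models, sampling, diagnostics, and posterior summaries."""

import numpy as np
import pytest

import seizprop as sp
from seizprop.posterior import SingleSeizureTarget
from seizprop.sampling import PosteriorSamples

SQRT2PI = np.sqrt(2 * np.pi)


def _obs(region_ids, status, onsets):
    return sp.SeizureObservation(
        list(region_ids), np.array(status, dtype=object), np.asarray(onsets, float)
    )


@pytest.fixture(scope="module")
def setup():
    W = sp.generate_network(6, seed=3)
    q = sp.ExcitationParams(-2.0, 0.0, 1.5, 2.0)
    rng = np.random.default_rng(4)
    c = rng.standard_normal(6)
    return W, q, c


class TestLogPosteriorSingle:
    def test_no_observations_equals_prior(self, setup):
        W, q, c = setup
        obs = _obs(W.region_ids, ["hidden"] * 6, [np.inf] * 6)
        expected = float(np.sum(-0.5 * c**2 - 0.5 * np.log(2 * np.pi)))
        assert np.isclose(sp.log_posterior_single(c, obs, W, q), expected)

    def test_saturated_nonseizing_term_is_gaussian_maximum(self, setup):
        W, q, _ = setup
        c = np.full(6, -6.0)  # so slow that simulated onsets exceed t_lim
        t = sp.simulate_onsets(W, q, c, t_max=90.0).t
        assert np.all(np.isinf(t))
        status = ["hidden"] * 6
        status[2] = "non-seizing"
        obs = _obs(W.region_ids, status, [np.inf] * 6)
        prior_only = _obs(W.region_ids, ["hidden"] * 6, [np.inf] * 6)
        delta = sp.log_posterior_single(c, obs, W, q) - sp.log_posterior_single(
            c, prior_only, W, q
        )
        assert np.isclose(delta, -np.log(5.0 * SQRT2PI))  # sigma_t = 5

    def test_shifting_one_observation_changes_only_its_term(self, setup):
        W, q, c = setup
        t = sp.simulate_onsets(W, q, c, t_max=90.0).t
        status = ["seizing" if ti < 90 else "non-seizing" for ti in t]
        onsets = np.where(t < 90, np.clip(t, 1e-3, None), np.inf)
        obs = _obs(W.region_ids, status, onsets)
        i = int(obs.seizing_idx[0])
        onsets2 = onsets.copy()
        onsets2[i] += 1.0
        obs2 = _obs(W.region_ids, status, onsets2)
        lp1 = sp.log_posterior_single(c, obs, W, q)
        lp2 = sp.log_posterior_single(c, obs2, W, q)
        m = min(t[i], 90.0)
        expected = (-0.5 * ((onsets2[i] - m) / 5.0) ** 2) - (
            -0.5 * ((onsets[i] - m) / 5.0) ** 2
        )
        assert np.isclose(lp2 - lp1, expected)

    def test_nonfinite_c_gives_minus_inf(self, setup):
        W, q, _ = setup
        obs = _obs(W.region_ids, ["hidden"] * 6, [np.inf] * 6)
        c = np.zeros(6)
        c[0] = np.nan
        assert sp.log_posterior_single(c, obs, W, q) == -np.inf


class TestLogPosteriorMulti:
    def test_single_seizure_reduces_to_single_plus_hyperprior(self, setup):
        W, q, c = setup
        obs, _ = sp.generate_seizure(W, q, 0.2, 3.0, seed=9)
        data = sp.MultiSeizureData([(obs, W)])
        qv = q.as_array()
        lp_multi = sp.log_posterior_multi(qv, [c], data)
        lp_single = sp.log_posterior_single(c, obs, W, q)
        hyper = lp_multi - lp_single
        # hyperprior: 2 normals + 2 half-normals with sigma_q = 30
        sq = 30.0
        expected = sum(
            -0.5 * (v / sq) ** 2 - np.log(sq * SQRT2PI) for v in qv[:2]
        ) + sum(
            -0.5 * (v / sq) ** 2 + 0.5 * np.log(2 / np.pi) - np.log(sq) for v in qv[2:]
        )
        assert np.isclose(hyper, expected)

    def test_negative_starred_parameter_unsupported(self, setup):
        W, q, c = setup
        obs, _ = sp.generate_seizure(W, q, 0.2, 3.0, seed=9)
        data = sp.MultiSeizureData([(obs, W)])
        assert sp.log_posterior_multi([0, 0, -0.1, 0], [c], data) == -np.inf

    def test_duplicating_a_seizure_doubles_its_data_terms(self, setup):
        W, q, c = setup
        obs, _ = sp.generate_seizure(W, q, 0.2, 3.0, seed=9)
        one = sp.MultiSeizureData([(obs, W)])
        two = sp.MultiSeizureData([(obs, W), (obs, W)])
        qv = q.as_array()
        lp1 = sp.log_posterior_multi(qv, [c], one)
        lp2 = sp.log_posterior_multi(qv, [c, c], two)
        lp_single = sp.log_posterior_single(c, obs, W, q)
        assert np.isclose(lp2 - lp1, lp_single)


class TestGradients:
    def test_gradient_matches_finite_differences(self, wellposed_seizure):
        """Analytic gradients agree with central differences away from
        event-order switch points (detected by FD self-consistency)."""
        W, obs, _ = wellposed_seizure
        target = SingleSeizureTarget(obs, W, sp.DEFAULT_TRUE_Q)
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(20):
            c = rng.standard_normal(20)
            _, g = target.logp_grad(c)
            for j in rng.choice(20, size=3, replace=False):
                fd = {}
                for eps in (1e-5, 2e-5):
                    cp, cm = c.copy(), c.copy()
                    cp[j] += eps
                    cm[j] -= eps
                    fd[eps] = (target.logp(cp) - target.logp(cm)) / (2 * eps)
                a, b = fd[1e-5], fd[2e-5]
                if abs(a - b) > 1e-3 * (abs(a) + 1e-6):
                    continue  # near an event-order switch; derivative kinks
                assert abs(g[j] - a) < 1e-4 * (abs(a) + 1e-3)
                checked += 1
        assert checked >= 20


class TestSampling:
    def test_prior_recovery(self, prior_fit):
        c = prior_fit.flat()
        assert np.all(np.abs(c.mean(axis=0)) < 0.15)
        assert np.all(np.abs(c.std(axis=0) - 1.0) < 0.15)

    def test_seed_determinism(self, wellposed_seizure):
        W, obs, _ = wellposed_seizure
        kw = dict(chains=2, warmup=100, draws=100, seed=77)
        a = sp.sample_single(obs, W, sp.DEFAULT_TRUE_Q, **kw)
        b = sp.sample_single(obs, W, sp.DEFAULT_TRUE_Q, **kw)
        assert np.array_equal(a.draws, b.draws)

    def test_noiseless_posterior_centers_on_exact_inversion(self):
        """With a fully observed noiseless seizure the posterior must cover
        the unique exact solution for every seizing region."""
        W = sp.generate_network(12, seed=21)
        q = sp.DEFAULT_TRUE_Q
        rng = np.random.default_rng(22)
        c_true = rng.standard_normal(12)
        t = sp.simulate_onsets(W, q, c_true).t
        status = ["seizing" if ti < 90 else "non-seizing" for ti in t]
        onsets = np.where(t < 90, t, np.inf)
        obs = _obs(W.region_ids, status, onsets)
        fit = sp.sample_single(obs, W, q, chains=2, warmup=500, draws=500, seed=23)
        c_inv = sp.invert_excitabilities(W, q, t)
        draws = fit.flat()
        for i in np.flatnonzero(np.asarray(status, object) == "seizing"):
            mean, sd = draws[:, i].mean(), draws[:, i].std()
            assert abs(mean - c_inv[i]) < 3 * sd

    def test_nuts_and_ensemble_posteriors_agree(self):
        """Dual-route check: the gradient-based sampler and the affine-
        invariant ensemble sampler target the same posterior."""
        W = sp.generate_network(5, seed=31)
        obs, _ = sp.generate_seizure(W, sp.DEFAULT_TRUE_Q, 0.2, 5.0, seed=32)
        a = sp.sample_single(obs, W, sp.DEFAULT_TRUE_Q, chains=2, warmup=500,
                             draws=500, seed=33)
        b = sp.sample_single(obs, W, sp.DEFAULT_TRUE_Q, chains=2, warmup=2000,
                             draws=2000, seed=34, method="ensemble")
        ma, mb = a.flat().mean(axis=0), b.flat().mean(axis=0)
        sa = a.flat().std(axis=0)
        assert np.all(np.abs(ma - mb) < 0.35 * np.maximum(sa, 0.3))

    def test_simulation_based_calibration_of_single_seizure_model(self):
        """When data are generated exactly from the statistical model (all
        regions seize well before t_lim, unclipped Gaussian onset noise), the
        rank of the true excitability among posterior draws is uniform and
        the 90% credible interval covers the truth at its nominal rate."""
        q = sp.ExcitationParams(-1.0, 0.5, 1.5, 1.0)  # fast, always-seizing
        n = 5
        W = sp.generate_network(n, seed=123)
        assert sp.simulate_onsets(W, q, np.full(n, -4.0)).t.max() < 60.0
        rng = np.random.default_rng(9)
        ranks, covered = [], 0
        M = 60
        for m in range(M):
            c_true = rng.standard_normal(n)
            t = sp.simulate_onsets(W, q, c_true).t
            tt = np.maximum(t + 5.0 * rng.standard_normal(n), 1e-3)
            obs = _obs(W.region_ids, ["seizing"] * n, tt)
            fit = sp.sample_single(obs, W, q, chains=2, warmup=300, draws=300,
                                   seed=10_000 + m)
            draws = fit.flat()
            for i in range(n):
                ranks.append((draws[:, i] < c_true[i]).mean())
                lo, hi = np.percentile(draws[:, i], [5, 95])
                covered += int(lo <= c_true[i] <= hi)
        ranks = np.asarray(ranks)
        assert abs(ranks.mean() - 0.5) < 0.05
        assert (ranks < 0.05).mean() < 0.12 and (ranks > 0.95).mean() < 0.12
        assert 0.8 <= covered / (M * n) <= 0.97

    def test_two_folds_from_same_dynamics_overlap(self):
        """Two disjoint cohorts generated from one q give overlapping 90%
        hyperparameter intervals."""
        q_true = sp.DEFAULT_TRUE_Q
        fits = []
        for fold in range(2):
            spec = sp.SyntheticCohortSpec(
                n_regions=10, n_patients=5, seizures_per_patient=2,
                true_q=q_true, seed=500 + fold,
            )
            data, _ = sp.generate_cohort(spec)
            fits.append(sp.sample_multi(data, chains=2, warmup=400, draws=400,
                                        seed=600 + fold))
        for i in range(4):
            lo0, hi0 = np.percentile(fits[0].flat()[:, i], [5, 95])
            lo1, hi1 = np.percentile(fits[1].flat()[:, i], [5, 95])
            assert max(lo0, lo1) <= min(hi0, hi1), f"q component {i} disjoint"


class TestDiagnostics:
    def _fake(self, draws):
        ch, n, d = draws.shape
        return PosteriorSamples(draws, [f"p{i}" for i in range(d)],
                                np.einsum("cnd->cn", draws**2) * -0.5)

    def test_iid_normal_chains_have_unit_rhat(self):
        rng = np.random.default_rng(0)
        s = self._fake(rng.standard_normal((4, 500, 3)))
        rhat, ess, stuck = sp.diagnostics(s)
        assert np.all((rhat > 0.99) & (rhat < 1.02))
        assert not stuck.any()

    def test_constant_chains_flagged_stuck(self):
        draws = np.ones((2, 100, 2))
        s = PosteriorSamples(draws, ["a", "b"], np.zeros((2, 100)))
        rhat, ess, stuck = sp.diagnostics(s)
        assert stuck.all() and s.all_stuck()
        assert np.all(np.isnan(rhat))

    def test_duplicated_chain_ess_within_total(self):
        rng = np.random.default_rng(1)
        one = rng.standard_normal((1, 400, 2))
        s = self._fake(np.concatenate([one, one], axis=0))
        _, ess, _ = sp.diagnostics(s)
        assert np.all(ess <= 2 * 400)

    def test_single_chain_rejected(self):
        s = self._fake(np.random.default_rng(2).standard_normal((1, 50, 2)))
        with pytest.raises(ValueError):
            sp.diagnostics(s)


class TestSummaries:
    def test_recruitment_probability_monotone_and_calibrated(self):
        rng = np.random.default_rng(5)
        onsets = rng.uniform(10, 80, size=(400, 3))
        grid = np.linspace(0, 100, 51)
        r = sp.recruitment_probability(onsets, grid)
        assert r.shape == (3, 51)
        assert np.all(np.diff(r, axis=1) >= 0)
        assert np.all(r[:, 0] == 0.0)
        med = np.median(onsets[:, 1])
        r_med = sp.recruitment_probability(onsets, [med])[1, 0]
        assert abs(r_med - 0.5) < 0.05

    def test_recruitment_tends_to_one(self, wellposed_fit):
        W, obs, truth, fit = wellposed_fit
        t_draws = sp.posterior_onsets(fit, W, sp.DEFAULT_TRUE_Q, t_max=np.inf)
        r = sp.recruitment_probability(t_draws, [1e9])
        assert np.all(r == 1.0)  # every onset finite when t_max is unbounded

    def test_observed_region_recruitment_jumps_near_observation(self, wellposed_fit):
        W, obs, truth, fit = wellposed_fit
        t_draws = sp.posterior_onsets(fit, W, sp.DEFAULT_TRUE_Q, t_max=np.inf)
        i = int(obs.seizing_idx[0])
        t_obs = obs.onset_s[i]
        r = sp.recruitment_probability(t_draws, [t_obs - 15, t_obs + 15])
        assert r[i, 0] < 0.5 < r[i, 1]

    def test_high_excitability_prior_tail(self):
        rng = np.random.default_rng(6)
        draws = rng.standard_normal((200_000, 1))
        p = sp.high_excitability_probability(draws, c_h=2.0)
        assert abs(p[0] - 0.02275) < 0.002

    def test_high_excitability_degenerate(self):
        draws = np.full((100, 2), -1.0)
        assert np.all(sp.high_excitability_probability(draws) == 0.0)


class TestPosteriorPredictive:
    def test_huge_rates_seize_everything(self):
        W = sp.generate_network(6, seed=8)
        q = sp.ExcitationParams(5.0, 5.0, 0.0, 0.0)  # rates >= e^5 everywhere
        out = sp.posterior_predictive_ensemble(q, [W], n_seizures=5, n_reps=10, seed=1)
        assert np.all(out["per_rep"]["fraction_seizing"] == 1.0)

    def test_seed_reproducibility(self):
        W = sp.generate_network(6, seed=8)
        a = sp.posterior_predictive_ensemble(sp.DEFAULT_TRUE_Q, [W], 5, n_reps=5, seed=3)
        b = sp.posterior_predictive_ensemble(sp.DEFAULT_TRUE_Q, [W], 5, n_reps=5, seed=3)
        for k in a["per_rep"]:
            assert np.array_equal(a["per_rep"][k], b["per_rep"][k], equal_nan=True)

    def test_split_envelopes_contain_full_run_mean(self):
        W = sp.generate_network(10, seed=9)
        full = sp.posterior_predictive_ensemble(sp.DEFAULT_TRUE_Q, [W], 10,
                                                n_reps=100, seed=10)
        halves = [
            sp.posterior_predictive_ensemble(sp.DEFAULT_TRUE_Q, [W], 10,
                                             n_reps=50, seed=s)
            for s in (11, 12)
        ]
        for k, v in full["per_rep"].items():
            mean = np.nanmean(v)
            lo = min(h["envelope_5_95"][k][0] for h in halves)
            hi = max(h["envelope_5_95"][k][1] for h in halves)
            assert lo <= mean <= hi
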