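"""Posterior summaries: recruitment probabilities, epileptogenicity, PPC.

The recruitment probability r_i(t) = p(t_i <= t) is the posterior
probability that region i has started seizing by time t, estimated as the
fraction of posterior onset-time draws at or below t.  The probability of
high excitability p(c_i > c_h) with c_h = 2 scores candidate epileptogenic
regions: under the standard-normal prior a region exceeds c_h with
probability 1 - Phi(2) ~ 0.0228, i.e. about 3.69 of 162 regions by chance.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .connectome import Connectome
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .dynamics import _q_array
from .sampling import PosteriorSamples

__all__ = [
    "posterior_onsets",
    "recruitment_probability",
    "high_excitability_probability",
    "posterior_predictive_ensemble",
]


def _c_draws(samples) -> np.ndarray:
    if isinstance(samples, PosteriorSamples):
        return samples.flat()
    return np.asarray(samples, dtype=float)


def posterior_onsets(samples, W: Connectome, q, t_max: float = np.inf) -> np.ndarray:
    """Simulate the propagation model for every posterior excitability draw.

    Returns an (n_draws, n_regions) array of onset times (+inf for regions
    unseized at t_max)."""
    C = _c_draws(samples)
    return _kernels.sim_event_batch(W.weights, _q_array(q), C, float(t_max))


def recruitment_probability(onset_draws: np.ndarray, time_grid) -> np.ndarray:
    """r_i(t) = fraction of draws with t_i <= t on a time grid.

    ``onset_draws`` is (n_draws, n_regions); the result is
    (n_regions, len(time_grid)), nondecreasing along the time axis with
    r_i(0) = 0."""
    t = np.atleast_1d(np.asarray(time_grid, dtype=float))
    return (onset_draws[:, :, None] <= t[None, None, :]).mean(axis=0)


def high_excitability_probability(samples, c_h: float = 2.0) -> np.ndarray:
    """Monte-Carlo estimate of p(c_i > c_h) per region."""
    C = _c_draws(samples)
    return (C > c_h).mean(axis=0)


def posterior_predictive_ensemble(
    q,
    connectomes: list[Connectome],
    n_seizures: int,
    *,
    n_reps: int = 100,
    seed,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Simulate repeated ensembles of seizures under fixed hyperparameters.

    For each repetition, ``n_seizures`` seizures are simulated with prior
    excitabilities c ~ N(0, 1) on connectomes cycled from the given list.
    Per seizure the fraction of seizing regions (onset < t_lim), the SD of
    the seizing onset times, and their 10th/50th/90th percentiles are
    recorded; per repetition these are averaged over the ensemble.  Returns
    the per-rep arrays and their 5-95 percentile envelopes.
    """
    rng = np.random.default_rng(seed)
    qv = _q_array(q)
    t_lim = constants.t_lim
    stat_names = ["fraction_seizing", "onset_sd", "onset_p10", "onset_p50", "onset_p90"]
    per_rep = {k: np.full(n_reps, np.nan) for k in stat_names}
    for rep in range(n_reps):
        vals = {k: [] for k in stat_names}
        for s in range(n_seizures):
            W = connectomes[s % len(connectomes)]
            c = rng.standard_normal(W.n_regions)
            t = _kernels.sim_event(W.weights, qv, c, t_lim)
            seizing = t[t < t_lim]
            vals["fraction_seizing"].append(len(seizing) / W.n_regions)
            if len(seizing) >= 2:
                vals["onset_sd"].append(float(np.std(seizing)))
            if len(seizing) >= 1:
                p10, p50, p90 = np.percentile(seizing, [10, 50, 90])
                vals["onset_p10"].append(p10)
                vals["onset_p50"].append(p50)
                vals["onset_p90"].append(p90)
        for k in stat_names:
            if vals[k]:
                per_rep[k][rep] = float(np.mean(vals[k]))
    envelopes = {
        k: tuple(np.nanpercentile(v, [5, 95])) for k, v in per_rep.items()
    }
    return {"per_rep": per_rep, "envelope_5_95": envelopes, "n_reps": n_reps}
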