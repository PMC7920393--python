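"""Prediction-accuracy measures, LOO cross-validation, resection analyses.

State prediction accuracy of a region is the posterior probability of its
ground-truth seizing/non-seizing state, approximated by the fraction of
posterior onset draws on the correct side of t_lim.  Onset prediction
accuracy is the fraction of draws within T seconds of the ground-truth
onset, evaluated only for seizing regions with onset below t_lim - T (to
avoid the border effect).  Two model-free baselines replace the posterior
draw set: the unweighted estimate uses the observed onsets of all other
observed regions, and the weighted estimate additionally weights region j
by the connection strength w_ij + w_ji.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome, apply_resection
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .observations import SeizureObservation
from .sampling import sample_single
from .summaries import posterior_onsets, recruitment_probability

__all__ = [
    "state_prediction_accuracy",
    "onset_prediction_accuracy",
    "unweighted_estimate",
    "weighted_estimate",
    "run_loo",
    "ResectionScenario",
    "precision_recall_curve",
    "VirtualResectionResult",
    "virtual_resection",
    "permutation_feature_importance",
]

logger = logging.getLogger(__name__)


def state_prediction_accuracy(onset_draws, truth_seizing: bool, t_lim: float = 90.0) -> float:
    """Fraction of onset draws with t < t_lim (seizing truth) or t >= t_lim."""
    t = np.asarray(onset_draws, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one onset draw")
    frac_seizing = float((t < t_lim).mean())
    return frac_seizing if truth_seizing else 1.0 - frac_seizing


def onset_prediction_accuracy(
    onset_draws, truth_onset: float, T: float = 5.0, t_lim: float = 90.0
) -> float | None:
    """Fraction of draws within T of the true onset; None when the truth is
    too close to t_lim (t >= t_lim - T) for the measure to be meaningful."""
    if not truth_onset < t_lim - T:
        return None
    t = np.asarray(onset_draws, dtype=float)
    return float((np.abs(t - truth_onset) < T).mean())


def _others(obs: SeizureObservation, i: int):
    idx = obs.observed_idx
    idx = idx[idx != i]
    if len(idx) == 0:
        raise ValueError("the estimates need at least one other observed region")
    return idx, obs.onset_s[idx]  # non-seizing enter as +inf


def unweighted_estimate(
    obs: SeizureObservation,
    i: int,
    truth_seizing: bool,
    truth_onset: float | None = None,
    t_lim: float = 90.0,
    T: float = 5.0,
):
    """Baseline accuracies using the other observed onsets as the draw set."""
    _, t_others = _others(obs, i)
    state_pa = state_prediction_accuracy(t_others, truth_seizing, t_lim)
    onset_pa = None
    if truth_seizing and truth_onset is not None:
        onset_pa = onset_prediction_accuracy(t_others, truth_onset, T, t_lim)
    return state_pa, onset_pa


def weighted_estimate(
    obs: SeizureObservation,
    W: Connectome,
    i: int,
    truth_seizing: bool,
    truth_onset: float | None = None,
    t_lim: float = 90.0,
    T: float = 5.0,
):
    """Connection-weighted baseline: region j counts with weight w_ij + w_ji."""
    idx, t_others = _others(obs, i)
    w = W.weights[i, idx] + W.weights[idx, i]
    total = w.sum()
    if total <= 0:
        logger.warning("weighted estimate undefined for region %d: zero total weight", i)
        return None, None
    w = w / total
    frac_seizing = float(np.sum(w * (t_others < t_lim)))
    state_pa = frac_seizing if truth_seizing else 1.0 - frac_seizing
    onset_pa = None
    if truth_seizing and truth_onset is not None and truth_onset < t_lim - T:
        onset_pa = float(np.sum(w * (np.abs(t_others - truth_onset) < T)))
    return state_pa, onset_pa


def run_loo(
    obs: SeizureObservation,
    W: Connectome,
    q,
    *,
    seed,
    chains: int = 2,
    warmup: int = 500,
    draws: int = 500,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    method: str = "nuts",
    **sampler_kwargs,
) -> pd.DataFrame:
    """Leave-one-out validation of one seizure.

    For every observed region the single-seizure model is refitted with that
    region's observation hidden, and the posterior prediction is scored
    against the left-out truth alongside the unweighted and weighted
    estimates.  ``q`` must come from a fit that did not use this seizure.
    Fits with all chains stuck are excluded (logged).  Returns a long-format
    frame with one row per (region, method).
    """
    rows = []
    t_lim, T = constants.t_lim, constants.T
    rng_root = np.random.SeedSequence(seed)
    for i, ss in zip(obs.observed_idx, rng_root.spawn(len(obs.observed_idx))):
        truth_seizing = obs.status[i] == "seizing"
        truth_onset = float(obs.onset_s[i]) if truth_seizing else None
        loo_obs = obs.hide_region(int(i))
        fit = sample_single(
            loo_obs, W, q, chains=chains, warmup=warmup, draws=draws,
            seed=int(ss.generate_state(1)[0] % (2**31)), constants=constants,
            method=method, **sampler_kwargs,
        )
        if fit.all_stuck():
            logger.warning("all chains stuck for left-out region %s; excluded",
                           obs.region_ids[int(i)])
            continue
        t_draws = posterior_onsets(fit, W, q, t_max=np.inf)[:, int(i)]
        inf_state = state_prediction_accuracy(t_draws, truth_seizing, t_lim)
        inf_onset = (
            onset_prediction_accuracy(t_draws, truth_onset, T, t_lim)
            if truth_seizing else None
        )
        est_state, est_onset = unweighted_estimate(
            obs, int(i), truth_seizing, truth_onset, t_lim, T
        )
        west_state, west_onset = weighted_estimate(
            obs, W, int(i), truth_seizing, truth_onset, t_lim, T
        )
        for method_name, spa, opa in (
            ("inference", inf_state, inf_onset),
            ("unweighted", est_state, est_onset),
            ("weighted", west_state, west_onset),
        ):
            rows.append(
                {
                    "region": obs.region_ids[int(i)],
                    "truth_state": "seizing" if truth_seizing else "non-seizing",
                    "truth_onset": truth_onset if truth_onset is not None else np.inf,
                    "method": method_name,
                    "state_pa": spa,
                    "onset_pa": opa,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ResectionScenario:
    """Resected region set (extent > 50%, strict) with the surgery outcome."""

    resected: set[str]
    engel: str | None = None  # "I".."IV"

    @classmethod
    def from_fractions(
        cls, region_ids: Sequence[str], fractions: Sequence[float], engel: str | None = None
    ) -> "ResectionScenario":
        resected = {
            str(r) for r, f in zip(region_ids, fractions) if f > 0.5
        }
        return cls(resected, engel)

    @classmethod
    def from_csv(cls, path: str | Path, engel: str | None = None) -> "ResectionScenario":
        df = pd.read_csv(path)
        return cls.from_fractions(
            df["region_id"].astype(str), df["resected_fraction"].astype(float), engel
        )


def precision_recall_curve(
    p_high: np.ndarray,
    region_ids: Sequence[str],
    relevant: set[str],
    thresholds=None,
    *,
    drop_empty: bool = True,
) -> pd.DataFrame:
    """Precision and recall of {i : p_i > p_t} against the relevant set.

    Precision at zero predictions is reported as 1 with ``no_predictions``
    flagged; such points are dropped by default (``drop_empty``).
    """
    if not relevant:
        raise ValueError("relevant set must be nonempty")
    p = np.asarray(p_high, dtype=float)
    ids = [str(r) for r in region_ids]
    rel = np.array([r in relevant for r in ids])
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    rows = []
    for p_t in np.asarray(thresholds, dtype=float):
        pred = p > p_t
        tp = int(np.sum(pred & rel))
        fp = int(np.sum(pred & ~rel))
        fn = int(np.sum(~pred & rel))
        empty = (tp + fp) == 0
        precision = 1.0 if empty else tp / (tp + fp)
        recall = tp / (tp + fn)
        rows.append(
            {
                "threshold": p_t, "precision": precision, "recall": recall,
                "tp": tp, "fp": fp, "fn": fn, "no_predictions": empty,
            }
        )
    df = pd.DataFrame(rows)
    if drop_empty:
        df = df[~df["no_predictions"]].reset_index(drop=True)
    return df


@dataclass
class VirtualResectionResult:
    n_preop: float
    n_postop: float
    relative_reduction: float
    mean_seizure_probability_preop: float
    mean_seizure_probability_postop: float

    @property
    def probability_decrease(self) -> float:
        """Thresholding-free variant: drop in mean seizure probability."""
        return self.mean_seizure_probability_preop - self.mean_seizure_probability_postop


def virtual_resection(
    W: Connectome,
    resected: Sequence[str],
    c_draws: np.ndarray,
    q,
    t_lim: float = 90.0,
) -> VirtualResectionResult:
    """Simulate surgery: remove the resected set and re-run the inferred model.

    For every posterior excitability draw the dynamics is simulated on the
    original network and on the resected subnetwork (with c restricted to the
    survivors).  A region counts as seizing when its recruitment probability
    at t_lim exceeds 50% (strict).  n_preop is counted over all regions of
    the original network; n_postop over the surviving regions only.  The
    thresholding-free variant reports the mean recruitment probability over
    all original regions, with resected regions contributing 0 post-op.
    """
    c_draws = np.atleast_2d(np.asarray(c_draws, dtype=float))
    W_post = apply_resection(W, resected)
    keep = [i for i, r in enumerate(W.region_ids) if r not in set(map(str, resected))]

    t_pre = posterior_onsets(c_draws, W, q, t_max=np.inf)
    r_pre = recruitment_probability(t_pre, [t_lim])[:, 0]
    t_post = posterior_onsets(c_draws[:, keep], W_post, q, t_max=np.inf)
    r_post = recruitment_probability(t_post, [t_lim])[:, 0]

    n_pre = int(np.sum(r_pre > 0.5))
    n_post = int(np.sum(r_post > 0.5))
    rel = (n_pre - n_post) / n_pre if n_pre > 0 else 0.0
    n = W.n_regions
    return VirtualResectionResult(
        n_preop=n_pre,
        n_postop=n_post,
        relative_reduction=rel,
        mean_seizure_probability_preop=float(r_pre.mean()),
        mean_seizure_probability_postop=float(r_post.sum() / n),
    )


def aggregate_patient_reduction(reductions: Sequence[float], how: str = "mean") -> float:
    """Combine per-seizure relative reductions for one patient."""
    agg = {"mean": np.mean, "min": np.min}[how]
    return float(agg(np.asarray(reductions, dtype=float)))


def compare_outcome_groups(
    reductions: dict[str, float], good_classes: tuple[str, ...] = ("I", "II")
) -> dict:
    """Convenience report: Mann-Whitney U comparing per-patient virtual-
    resection reductions between good-outcome (Engel I/II) and poor-outcome
    patients.  ``reductions`` maps patient id to (reduction, engel) pairs or
    is given as {patient: (value, engel_class)}."""
    from scipy.stats import mannwhitneyu

    good, poor = [], []
    for value, engel in reductions.values():
        (good if engel in good_classes else poor).append(value)
    if not good or not poor:
        raise ValueError("both outcome groups must be nonempty")
    stat = mannwhitneyu(good, poor, alternative="greater")
    return {
        "U": float(stat.statistic), "p": float(stat.pvalue),
        "n_good": len(good), "n_poor": len(poor),
    }


def permutation_feature_importance(
    model,
    X,
    y,
    *,
    K: int = 30,
    seed,
    score: Callable | None = None,
) -> pd.Series:
    """Permutation importance i_j = s - mean_k s_{k,j} of a fitted regressor.

    ``model`` is any object with ``predict`` (and ``score`` unless a scoring
    function ``score(model, X, y)`` is supplied; the default score is the
    model's own, R^2 for regressors).  Each feature column is reshuffled K
    times independently.
    """
    rng = np.random.default_rng(seed)
    X_df = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y)
    if score is None:
        score = lambda m, Xv, yv: m.score(Xv, yv)  # noqa: E731
    s = score(model, X_df, y)
    importances = {}
    for col in X_df.columns:
        vals = np.empty(K)
        for k in range(K):
            Xp = X_df.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            vals[k] = score(model, Xp, y)
        importances[col] = s - vals.mean()
    return pd.Series(importances, name="importance")
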