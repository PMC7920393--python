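"""Log posterior densities of the single- and multi-seizure models.

Single-seizure model (hyperparameters q fixed):

    c ~ Normal(0, 1)            per region
    t = P_{W,q}(c)              event-driven forward simulation
    t~_seizing    ~ Normal(min(t, t_lim), sigma_t)
    t_lim         ~ Normal(min(t, t_lim), sigma_t)   for non-seizing regions

Multi-seizure model adds the hyperpriors

    q_aa, q_ab    ~ Normal(0, sigma_q)
    q_ba*, q_bb*  ~ HalfNormal(sigma_q)

and couples the seizures only through q.  Hidden regions contribute no
likelihood term.  The non-seizing term is the one-sided soft penalty exactly
as written: once the simulated onset exceeds t_lim it saturates at the
Gaussian maximum (no renormalization).

Gradients are exact within the realized event order (the onset map is
piecewise smooth; order switches are measure zero).  For gradient-based
sampling the half-normal parameters are log-transformed to the unconstrained
scale with the usual Jacobian correction.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .connectome import Connectome
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .dynamics import ExcitationParams, _q_array
from .observations import MultiSeizureData, SeizureObservation

__all__ = ["log_posterior_single", "log_posterior_multi", "SingleSeizureTarget", "MultiSeizureTarget"]

_LOG_2PI = math.log(2.0 * math.pi)


def _obs_arrays(obs: SeizureObservation):
    return (
        obs.seizing_idx.astype(np.int64),
        obs.t_seizing.astype(float),
        obs.nonseizing_idx.astype(np.int64),
    )


def log_posterior_single(
    c,
    obs: SeizureObservation,
    W: Connectome,
    q,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Unnormalized log posterior of the excitabilities for one seizure."""
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        return -np.inf
    s_idx, s_t, ns_idx = _obs_arrays(obs)
    return float(
        _kernels.logp_single(
            W.weights, _q_array(q), c, s_idx, s_t, ns_idx, constants.sigma_t, constants.t_lim
        )
    )


def _log_hyperprior(q: np.ndarray, sigma_q: float) -> float:
    """Normal(0, sigma_q) on q_aa, q_ab; HalfNormal(sigma_q) on the starred."""
    if q[2] < 0 or q[3] < 0:
        return -np.inf
    lp = 0.0
    for v in q[:2]:
        lp += -0.5 * (v / sigma_q) ** 2 - math.log(sigma_q) - 0.5 * _LOG_2PI
    for v in q[2:]:
        lp += (
            -0.5 * (v / sigma_q) ** 2
            + 0.5 * math.log(2.0 / math.pi)
            - math.log(sigma_q)
        )
    return lp


def log_posterior_multi(
    q,
    c_list,
    data: MultiSeizureData,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Unnormalized log posterior of (q, {c_k}) for a seizure cohort."""
    q = np.asarray(q, dtype=float)
    lp = _log_hyperprior(q, constants.sigma_q)
    if not np.isfinite(lp):
        return lp
    if len(c_list) != data.n_seizures:
        raise ValueError("need one excitability vector per seizure")
    for c_k, (obs, W) in zip(c_list, data):
        lp += log_posterior_single(c_k, obs, W, q, constants)
    return float(lp)


class SingleSeizureTarget:
    """Differentiable target over c for one seizure; used by the samplers."""

    def __init__(
        self,
        obs: SeizureObservation,
        W: Connectome,
        q,
        constants: ModelConstants = DEFAULT_CONSTANTS,
    ):
        self.obs, self.W = obs, W
        self.q = _q_array(q)
        self.constants = constants
        self._s_idx, self._s_t, self._ns_idx = _obs_arrays(obs)
        self.dim = obs.n_regions
        self.param_names = [f"c[{r}]" for r in obs.region_ids]

    def logp(self, c: np.ndarray) -> float:
        return float(
            _kernels.logp_single(
                self.W.weights, self.q, c, self._s_idx, self._s_t, self._ns_idx,
                self.constants.sigma_t, self.constants.t_lim,
            )
        )

    def logp_grad(self, c: np.ndarray):
        lp, gc, _ = _kernels.logp_grad_single(
            self.W.weights, self.q, c, self._s_idx, self._s_t, self._ns_idx,
            self.constants.sigma_t, self.constants.t_lim,
        )
        return lp, gc

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(self.dim)  # prior draw

    def constrain(self, x: np.ndarray) -> np.ndarray:
        return x


class MultiSeizureTarget:
    """Differentiable target over (q_aa, q_ab, log q_ba*, log q_bb*, c_1..c_K).

    The half-normal parameters are sampled on the log scale; the Jacobian
    term log q* is added so the density on the constrained scale matches the
    printed model.  ``constrain`` maps an unconstrained vector back to
    (q_aa, q_ab, q_ba*, q_bb*, c...) for reporting.
    """

    def __init__(self, data: MultiSeizureData, constants: ModelConstants = DEFAULT_CONSTANTS):
        if data.n_seizures == 0:
            raise ValueError("empty cohort")
        self.data = data
        self.constants = constants
        self.n = data.n_regions
        self.K = data.n_seizures
        self.dim = 4 + self.K * self.n
        # stacked CSR-style arrays for the fused cohort kernel
        self._Ws = np.ascontiguousarray(np.stack([W.weights for _, W in data]))
        s_idx, s_t, ns_idx = [], [], []
        s_ptr, ns_ptr = [0], [0]
        for obs, _ in data:
            si, st, ni = _obs_arrays(obs)
            s_idx.append(si)
            s_t.append(st)
            ns_idx.append(ni)
            s_ptr.append(s_ptr[-1] + len(si))
            ns_ptr.append(ns_ptr[-1] + len(ni))
        self._s_idx = np.concatenate(s_idx) if s_idx else np.empty(0, np.int64)
        self._s_t = np.concatenate(s_t) if s_t else np.empty(0)
        self._ns_idx = np.concatenate(ns_idx) if ns_idx else np.empty(0, np.int64)
        self._s_ptr = np.asarray(s_ptr, dtype=np.int64)
        self._ns_ptr = np.asarray(ns_ptr, dtype=np.int64)
        self.param_names = ["q_aa", "q_ab", "q_ba_star", "q_bb_star"] + [
            f"c[{k},{r}]" for k in range(self.K) for r in data[k][0].region_ids
        ]

    def _split(self, x: np.ndarray):
        qu = x[:4]
        q = np.array([qu[0], qu[1], math.exp(qu[2]), math.exp(qu[3])])
        C = x[4:].reshape(self.K, self.n)
        return qu, q, C

    def logp_grad(self, x: np.ndarray):
        qu, q, C = self._split(x)
        sq = self.constants.sigma_q
        # hyperprior on the unconstrained scale (+ log-Jacobian q* = exp(u))
        lp = (
            -0.5 * (qu[0] / sq) ** 2
            - 0.5 * (qu[1] / sq) ** 2
            - 0.5 * (q[2] / sq) ** 2
            - 0.5 * (q[3] / sq) ** 2
            + qu[2]
            + qu[3]
        )
        grad = np.empty_like(x)
        grad[0] = -qu[0] / sq**2
        grad[1] = -qu[1] / sq**2
        grad[2] = 1.0 - (q[2] / sq) ** 2  # d/du of (u - exp(2u)/2sq^2)
        grad[3] = 1.0 - (q[3] / sq) ** 2
        lp_data, gC, gq_total = _kernels.logp_grad_cohort(
            self._Ws, q, np.ascontiguousarray(C),
            self._s_idx, self._s_t, self._s_ptr,
            self._ns_idx, self._ns_ptr,
            self.constants.sigma_t, self.constants.t_lim,
        )
        lp += lp_data
        grad[4:] = gC.ravel()
        grad[0] += gq_total[0]
        grad[1] += gq_total[1]
        grad[2] += gq_total[2] * q[2]  # chain rule through q* = exp(u)
        grad[3] += gq_total[3] * q[3]
        return float(lp), grad

    def logp(self, x: np.ndarray) -> float:
        return self.logp_grad(x)[0]

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        # moderate random inits: N(0,1) for q_aa, q_ab and log q*; prior for c
        x = np.empty(self.dim)
        x[:4] = rng.standard_normal(4)
        x[4:] = rng.standard_normal(self.K * self.n)
        return x

    def constrain(self, x: np.ndarray) -> np.ndarray:
        out = x.copy()
        out[2] = math.exp(x[2])
        out[3] = math.exp(x[3])
        return out

    def extract_q(self, constrained_draws: np.ndarray) -> np.ndarray:
        """(draws, dim) -> (draws, 4) hyperparameter draws."""
        return constrained_draws[..., :4]

    def point_estimate_q(self, constrained_draws: np.ndarray) -> ExcitationParams:
        """Posterior mean of each hyperparameter component."""
        q = constrained_draws[..., :4].reshape(-1, 4).mean(axis=0)
        return ExcitationParams.from_array(q)
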