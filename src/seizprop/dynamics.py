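"""The deterministic propagation model and its exact inversion.

A region i switches from the healthy to the seizure state when its slow
variable z_i, growing at the rate f_q(c_i, y_i) set by its excitability c_i
and its seizing-afferent input y_i = sum_j w_ij H(z_j - 1), crosses 1.  The
excitation function is a bilinear interpolant in (c, y) through four anchor
values, exponentiated to guarantee positivity:

    f_q(c, y) = exp(fhat_q(c, y)),

with anchors (c_a, c_b) = (-1, 1), (y_a, y_b) = (0, 1) and values
q_aa, q_ab, q_ba = q_aa + q_ba*, q_bb = q_ab + q_bb*.  The starred
parameters are nonnegative, which makes f_q nondecreasing in c, so larger
c is always "more excitable".  Outside the anchor square the same bilinear
formula extrapolates (c ~ N(0,1) routinely exceeds +-1).

Because the right-hand side is piecewise constant, the forward problem
P_{W,q}(c) = t has an exact event-driven solution, and with complete,
noiseless onset observations the inverse problem has a unique solution per
region, recovered here by bisection on the accumulated-growth equation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .connectome import Connectome

__all__ = [
    "ExcitationParams",
    "OnsetTimes",
    "excitation_value",
    "simulate_onsets",
    "simulate_dense",
    "classify_states",
    "invert_excitabilities",
]

# interpolation anchors of the bilinear excitation exponent
C_A, C_B, Y_A, Y_B = -1.0, 1.0, 0.0, 1.0


@dataclass(frozen=True)
class ExcitationParams:
    """Hyperparameters q = (q_aa, q_ab, q_ba*, q_bb*) of the excitation function."""

    q_aa: float
    q_ab: float
    q_ba_star: float
    q_bb_star: float

    def __post_init__(self) -> None:
        if self.q_ba_star < 0 or self.q_bb_star < 0:
            raise ValueError("q_ba_star and q_bb_star must be nonnegative")

    @property
    def q_ba(self) -> float:
        return self.q_aa + self.q_ba_star

    @property
    def q_bb(self) -> float:
        return self.q_ab + self.q_bb_star

    def as_array(self) -> np.ndarray:
        return np.array([self.q_aa, self.q_ab, self.q_ba_star, self.q_bb_star])

    @classmethod
    def from_array(cls, q: np.ndarray) -> "ExcitationParams":
        return cls(*(float(v) for v in np.asarray(q, dtype=float)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExcitationParams":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class OnsetTimes:
    """Per-region onset times in seconds; +inf marks "never seized by t_max"."""

    t: np.ndarray
    t_lim: float = 90.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(self.t <= 0):
            raise ValueError("onset times must be positive")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.t, dtype=dtype)

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path: str | Path, region_ids=None) -> None:
        ids = region_ids or [f"r{i}" for i in range(len(self.t))]
        pd.DataFrame({"region_id": ids, "onset_s": self.t}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, t_lim: float = 90.0):
        df = pd.read_csv(path)
        return cls(df["onset_s"].to_numpy(dtype=float), t_lim), df["region_id"].astype(str).tolist()


def _q_array(q) -> np.ndarray:
    if isinstance(q, ExcitationParams):
        return q.as_array()
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError("q must be an ExcitationParams or a length-4 array")
    if q[2] < 0 or q[3] < 0:
        raise ValueError("q_ba_star and q_bb_star must be nonnegative")
    return q


def _w_array(W) -> np.ndarray:
    if isinstance(W, Connectome):
        return W.weights
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if W.size and W.sum(axis=1).max() > 1.0 + 1e-9:
        raise ValueError("W is not normalized: some ingoing-weight sum exceeds 1")
    return W


def excitation_value(q, c, y):
    """Evaluate f_q(c, y) = exp(fhat_q(c, y)); vectorized over c and y.

    y must lie in [0, 1] (guaranteed by connectome normalization); c is
    unrestricted and extrapolated by the same bilinear form outside [-1, 1].
    """
    q = _q_array(q)
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((y < Y_A - 1e-9) | (y > Y_B + 1e-9)):
        raise ValueError("network input y must lie in [0, 1]")
    y = np.clip(y, Y_A, Y_B)  # tolerate roundoff from summed normalized weights
    if not np.all(np.isfinite(c)):
        raise ValueError("excitability c must be finite")
    qaa, qab = q[0], q[1]
    qba, qbb = q[0] + q[2], q[1] + q[3]
    fhat = (
        qaa * (C_B - c) * (Y_B - y)
        + qba * (c - C_A) * (Y_B - y)
        + qab * (C_B - c) * (y - Y_A)
        + qbb * (c - C_A) * (y - Y_A)
    ) / ((C_B - C_A) * (Y_B - Y_A))
    return np.exp(fhat)


def simulate_onsets(W, q, c, t_max: float = np.inf) -> OnsetTimes:
    """Exact event-driven solution of P_{W,q}(c) = t.

    Between events every z_i grows linearly; the next event is the minimum of
    (1 - z_i) / rate_i over non-seized regions.  Regions still unseized when
    the next event would exceed t_max receive +inf.  With t_max = inf every
    onset is finite because f_q > 0.
    """
    Wm, qv = _w_array(W), _q_array(q)
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("excitability c must be finite")
    if c.shape != (Wm.shape[0],):
        raise ValueError("c length must match the network size")
    t = _kernels.sim_event(Wm, qv, c, float(t_max))
    return OnsetTimes(t, t_lim=90.0 if not np.isfinite(t_max) else min(90.0, t_max))


def simulate_dense(W, q, c, dt: float = 1e-3, t_max: float = 200.0) -> OnsetTimes:
    """Fixed-step explicit-Euler integration; independent oracle for
    simulate_onsets.  Heaviside inputs are evaluated at the left endpoint;
    onset is the first grid time with z_i >= 1.  Converges to the
    event-driven solution as dt -> 0 (first order)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(t_max):
        raise ValueError("simulate_dense needs a finite t_max")
    Wm, qv = _w_array(W), _q_array(q)
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("excitability c must be finite")
    t = _kernels.sim_dense(Wm, qv, c, float(dt), float(t_max))
    return OnsetTimes(t, t_lim=min(90.0, t_max))


def classify_states(t, t_lim: float = 90.0) -> np.ndarray:
    """Boolean seizing state: True iff t_i < t_lim (boundary counts as
    non-seizing, matching the strict inequality of the state accuracy)."""
    tv = np.asarray(t, dtype=float)
    return tv < t_lim


class NonIdentifiableError(ValueError):
    """The inverse problem has no unique excitability solution."""


def invert_excitabilities(W, q, t_full, tol: float = 1e-10) -> np.ndarray:
    """Noiseless exact inversion: recover c from complete finite onset times.

    For region i the accumulated growth over the constant-input intervals
    before its onset must equal 1:

        sum_k exp(fhat_q(c_i, y^(k))) * dt_k = 1.

    The left side is continuous, strictly increasing in c_i (when
    q_ba* + q_bb* > 0) with range (0, inf), so a unique root exists; it is
    bracketed by geometric expansion from [-50, 50] and solved by bisection
    to |dc| < tol.  Onsets containing inf are rejected: the exact inversion
    is defined only for fully seizing, fully observed networks.
    """
    Wm, qv = _w_array(W), _q_array(q)
    t = np.asarray(t_full, dtype=float)
    if t.ndim != 1 or t.shape[0] != Wm.shape[0]:
        raise ValueError("t_full length must match the network size")
    if not np.all(np.isfinite(t)):
        raise ValueError(
            "exact inversion requires fully observed, fully seizing onsets (no inf)"
        )
    if qv[2] == 0 and qv[3] == 0:
        raise NonIdentifiableError(
            "f_q does not depend on c (q_ba* = q_bb* = 0): excitabilities are "
            "not identifiable from onset times"
        )
    n = Wm.shape[0]
    order = np.argsort(t, kind="stable")
    c_rec = np.empty(n)
    for i in range(n):
        # interval boundaries: onsets of regions that seized strictly before t_i
        earlier = order[t[order] < t[i]]
        bounds = np.concatenate(([0.0], t[earlier], [t[i]]))
        dts = np.diff(bounds)
        y = np.concatenate(([0.0], np.cumsum(Wm[i, earlier])))

        def growth(ci):
            return float(np.sum(excitation_value(qv, ci, y) * dts)) - 1.0

        lo, hi = -50.0, 50.0
        while growth(lo) > 0:
            lo *= 2.0
            if lo < -1e6:
                raise NonIdentifiableError(f"no root bracket found for region {i}")
        while growth(hi) < 0:
            hi *= 2.0
            if hi > 1e6:
                raise NonIdentifiableError(f"no root bracket found for region {i}")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if growth(mid) < 0:
                lo = mid
            else:
                hi = mid
        c_rec[i] = 0.5 * (lo + hi)
    return c_rec
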