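"""No-U-Turn sampler with dual-averaging step size and diagonal mass matrix.

Implementation of the slice-sampling NUTS variant (Hoffman & Gelman,
algorithm 3) with Stan-style warmup: an initial fast interval adapting only
the step size, a sequence of doubling slow windows estimating the diagonal
mass matrix from the warmup draws, and a terminal fast interval.  The target
object must provide ``logp_grad(x) -> (float, ndarray)``.

This sampler exists because the propagation model's posterior is explored
here with hand-derived gradients; it is deliberately minimal but follows the
published algorithm, including the divergence guard (energy error > 1000)
and the per-doubling U-turn criterion evaluated in the metric induced by the
mass matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["nuts_chain", "NutsChainResult"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the energy error


@dataclass
class NutsChainResult:
    draws: np.ndarray          # (n_draws, dim)
    logp: np.ndarray           # (n_draws,)
    divergences: int
    tree_depths: np.ndarray
    accept_stat: np.ndarray
    step_size: float
    inv_mass: np.ndarray
    warmup_draws: np.ndarray | None = field(default=None, repr=False)


def _kinetic(r: np.ndarray, inv_mass: np.ndarray) -> float:
    # overflow to +inf on a divergent trajectory is handled by the caller
    with np.errstate(over="ignore"):
        return 0.5 * float(np.dot(r * r, inv_mass))


def _find_reasonable_epsilon(target, x, lp, grad, inv_mass, rng) -> float:
    eps = 1.0
    r = rng.standard_normal(x.shape[0]) / np.sqrt(inv_mass)
    H0 = lp - _kinetic(r, inv_mass)
    x1, r1, lp1, _ = _leapfrog(target, x, r, grad, eps, inv_mass)
    H1 = lp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(H1):
        H1 = -np.inf
    a = 1.0 if H1 - H0 > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**a
        x1, r1, lp1, _ = _leapfrog(target, x, r, grad, eps, inv_mass)
        H1 = lp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(H1):
            H1 = -np.inf
        if a * (H1 - H0) <= a * math.log(0.5):
            break
    return eps


def _leapfrog(target, x, r, grad, eps, inv_mass):
    r_half = r + 0.5 * eps * grad
    x_new = x + eps * inv_mass * r_half
    lp, g_new = target.logp_grad(x_new)
    r_new = r_half + 0.5 * eps * g_new
    return x_new, r_new, lp, g_new


def _no_uturn(x_minus, x_plus, r_minus, r_plus, inv_mass) -> bool:
    dx = x_plus - x_minus
    return (np.dot(dx, inv_mass * r_minus) >= 0.0) and (
        np.dot(dx, inv_mass * r_plus) >= 0.0
    )


def nuts_chain(
    target,
    x0: np.ndarray,
    *,
    n_warmup: int = 500,
    n_draws: int = 500,
    seed,
    target_accept: float = 0.8,
    max_tree_depth: int = 10,
    keep_warmup: bool = False,
) -> NutsChainResult:
    """Run one NUTS chain from ``x0``; returns post-warmup draws."""
    rng = np.random.default_rng(seed)
    dim = x0.shape[0]
    inv_mass = np.ones(dim)
    x = np.asarray(x0, dtype=float).copy()
    lp, grad = target.logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial position has non-finite log density")

    eps = _find_reasonable_epsilon(target, x, lp, grad, inv_mass, rng)
    # dual averaging state
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # Stan-style warmup schedule
    init_buffer, term_buffer, base_window = 75, 50, 25
    if n_warmup < init_buffer + term_buffer + base_window:
        init_buffer = max(1, int(0.15 * n_warmup))
        term_buffer = max(1, int(0.1 * n_warmup))
    window_ends: list[int] = []
    w_start, w_size = init_buffer, base_window
    while w_start + w_size <= n_warmup - term_buffer:
        end = w_start + w_size
        if end + 2 * w_size > n_warmup - term_buffer:
            end = n_warmup - term_buffer
        window_ends.append(end)
        w_start, w_size = end, 2 * w_size

    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    total = n_warmup + n_draws
    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    depths = np.empty(n_draws, dtype=np.int64)
    accept = np.empty(n_draws)
    warm = np.empty((n_warmup, dim)) if keep_warmup else None
    n_div = 0
    da_count = 0

    for it in range(total):
        adapting = it < n_warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        H0 = lp - _kinetic(r0, inv_mass)
        logu = H0 - rng.exponential()

        x_minus = x_plus = x
        r_minus = r_plus = r0
        g_minus = g_plus = grad
        x_prop, lp_prop, g_prop = x, lp, grad
        n_good, depth, s = 1, 0, True
        alpha_sum, n_alpha = 0.0, 0
        diverged = False

        while s and depth < max_tree_depth:
            v = 1.0 if rng.random() < 0.5 else -1.0
            if v == 1.0:
                (x_plus, r_plus, g_plus, xc, lc, gc, n1, s1, a1, na1, div1) = _build(
                    target, x_plus, r_plus, g_plus, logu, v, depth, eps, H0, inv_mass, rng
                )
            else:
                (x_minus, r_minus, g_minus, xc, lc, gc, n1, s1, a1, na1, div1) = _build(
                    target, x_minus, r_minus, g_minus, logu, v, depth, eps, H0, inv_mass, rng
                )
            diverged = diverged or div1
            if s1 and n1 > 0 and rng.random() < n1 / max(n_good, 1):
                x_prop, lp_prop, g_prop = xc, lc, gc
            n_good += n1
            alpha_sum += a1
            n_alpha += na1
            s = s1 and _no_uturn(x_minus, x_plus, r_minus, r_plus, inv_mass)
            depth += 1

        x, lp, grad = x_prop, lp_prop, g_prop
        astat = alpha_sum / max(n_alpha, 1)

        if adapting:
            # dual averaging step-size update
            da_count += 1
            eta = 1.0 / (da_count + t0)
            h_bar = (1.0 - eta) * h_bar + eta * (target_accept - astat)
            log_eps = mu - math.sqrt(da_count) / gamma * h_bar
            w = da_count**-kappa
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if keep_warmup:
                warm[it] = x
            # mass-matrix accumulation inside slow windows
            if window_ends and it >= init_buffer:
                welford_n += 1
                delta = x - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (x - welford_mean)
                if it + 1 == window_ends[0]:
                    if welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        # Stan regularization toward unit mass
                        var = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                            5.0 / (welford_n + 5.0)
                        )
                        inv_mass = np.maximum(var, 1e-10)
                    window_ends.pop(0)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    # restart step-size adaptation around the current value
                    eps = _find_reasonable_epsilon(target, x, lp, grad, inv_mass, rng)
                    mu = math.log(10.0 * eps)
                    da_count, h_bar, log_eps_bar = 0, 0.0, 0.0
            if it + 1 == n_warmup:
                eps = math.exp(log_eps_bar) if da_count > 0 else eps
        else:
            k = it - n_warmup
            draws[k] = x
            logps[k] = lp
            depths[k] = depth
            accept[k] = astat
            if diverged:
                n_div += 1

    return NutsChainResult(
        draws=draws,
        logp=logps,
        divergences=n_div,
        tree_depths=depths,
        accept_stat=accept,
        step_size=eps,
        inv_mass=inv_mass,
        warmup_draws=warm,
    )


def _build(target, x, r, g, logu, v, depth, eps, H0, inv_mass, rng):
    """Recursive tree doubling.  Returns the outermost state in direction v,
    a candidate sample with its logp/grad, the number of slice-admissible
    states, the continue flag, accept statistics, and a divergence flag."""
    if depth == 0:
        x1, r1, lp1, g1 = _leapfrog(target, x, r, g, v * eps, inv_mass)
        H1 = lp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(H1):
            H1 = -np.inf
        n1 = 1 if logu <= H1 else 0
        diverged = (H0 - H1) > _MAX_DELTA_H if np.isfinite(H1) else True
        alpha = min(1.0, math.exp(min(H1 - H0, 0.0))) if np.isfinite(H1) else 0.0
        return x1, r1, g1, x1, lp1, g1, n1, not diverged, alpha, 1, diverged

    (x_out, r_out, g_out, xc, lc, gc, n1, s1, a1, na1, d1) = _build(
        target, x, r, g, logu, v, depth - 1, eps, H0, inv_mass, rng
    )
    if s1:
        (x_out2, r_out2, g_out2, xc2, lc2, gc2, n2, s2, a2, na2, d2) = _build(
            target, x_out, r_out, g_out, logu, v, depth - 1, eps, H0, inv_mass, rng
        )
        if n2 > 0 and rng.random() < n2 / max(n1 + n2, 1):
            xc, lc, gc = xc2, lc2, gc2
        if v == 1.0:
            ok = _no_uturn(x, x_out2, r, r_out2, inv_mass)
        else:
            ok = _no_uturn(x_out2, x, r_out2, r, inv_mass)
        s1 = s2 and ok
        n1 += n2
        a1 += a2
        na1 += na2
        d1 = d1 or d2
        x_out, r_out, g_out = x_out2, r_out2, g_out2
    return x_out, r_out, g_out, xc, lc, gc, n1, s1, a1, na1, d1
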