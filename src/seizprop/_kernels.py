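"""Numba kernels: event-driven propagation, gradients, dense oracle, likelihoods.

The propagation model is piecewise linear: between threshold crossings each
slow variable z_i grows at the constant rate exp(fhat(c_i, y_i)), where y_i
is the summed weight of currently-seizing afferents.  The exact solution is
therefore event-driven: repeatedly find the region whose z_i reaches 1 first,
advance, and update the inputs.  Because the right-hand side is constant
between events, onset times are piecewise-smooth functions of (c, q) and
their derivatives propagate exactly through the event cascade; the *_grad
kernels carry these tangents in forward mode (n + 4 directions: all
excitabilities plus the four raw excitation parameters).

Raw parameter order everywhere: (q_aa, q_ab, q_ba_star, q_bb_star) with
q_ba = q_aa + q_ba_star and q_bb = q_ab + q_bb_star.

The bilinear exponent is clipped to |fhat| <= 60 (rates between e-60 and
e+60 1/s) to keep the dynamics finite when samplers explore extreme q; the
clip zeroes the local gradient, which only happens far outside the region of
posterior mass.
"""

import numpy as np
from numba import njit

_FCLIP = 60.0


@njit(cache=True, inline="always")
def _fhat(qaa, qab, qbas, qbbs, c, y):
    qba = qaa + qbas
    qbb = qab + qbbs
    return 0.5 * (
        qaa * (1.0 - c) * (1.0 - y)
        + qab * (1.0 - c) * y
        + qba * (1.0 + c) * (1.0 - y)
        + qbb * (1.0 + c) * y
    )


@njit(cache=True)
def sim_event(W, q, c, t_max):
    """Exact event-driven onset times; +inf for regions unseized at t_max."""
    n = c.shape[0]
    t = np.full(n, np.inf)
    z = np.zeros(n)
    y = np.zeros(n)
    s = np.zeros(n)
    seized = np.zeros(n, np.bool_)
    T = 0.0
    for _ in range(n):
        best = -1
        btau = np.inf
        for i in range(n):
            if seized[i]:
                continue
            f = _fhat(q[0], q[1], q[2], q[3], c[i], y[i])
            if f > _FCLIP:
                f = _FCLIP
            elif f < -_FCLIP:
                f = -_FCLIP
            s[i] = np.exp(f)
            tau = (1.0 - z[i]) / s[i]
            if tau < btau:
                btau = tau
                best = i
        if best < 0:
            break
        E = T + btau
        if E > t_max:
            break
        for i in range(n):
            if not seized[i] and i != best:
                z[i] += s[i] * btau
        t[best] = E
        z[best] = 1.0
        seized[best] = True
        for i in range(n):
            y[i] += W[i, best]
        T = E
    return t


@njit(cache=True)
def sim_event_grad(W, q, c, t_max):
    """Onset times plus d t / d c (n x n) and d t / d q_raw (n x 4).

    Derivatives are taken within the realized event order (the map is smooth
    except where the order switches).  Regions unseized at t_max get +inf
    onsets and zero derivative rows.
    """
    n = c.shape[0]
    p = n + 4
    t = np.full(n, np.inf)
    dt = np.zeros((n, p))
    z = np.zeros(n)
    dz = np.zeros((n, p))
    y = np.zeros(n)
    s = np.zeros(n)
    dfc = np.zeros(n)          # d fhat / d c_i
    dfq = np.zeros((n, 4))     # d fhat / d q_raw
    seized = np.zeros(n, np.bool_)
    dT = np.zeros(p)
    dtau = np.zeros(p)
    T = 0.0
    for _ in range(n):
        best = -1
        btau = np.inf
        for i in range(n):
            if seized[i]:
                continue
            f = _fhat(q[0], q[1], q[2], q[3], c[i], y[i])
            if f > _FCLIP or f < -_FCLIP:
                f = min(max(f, -_FCLIP), _FCLIP)
                s[i] = np.exp(f)
                dfc[i] = 0.0
                dfq[i, 0] = 0.0
                dfq[i, 1] = 0.0
                dfq[i, 2] = 0.0
                dfq[i, 3] = 0.0
            else:
                s[i] = np.exp(f)
                yi = y[i]
                ci = c[i]
                dfc[i] = 0.5 * (q[2] * (1.0 - yi) + q[3] * yi)
                dfq[i, 0] = 1.0 - yi
                dfq[i, 1] = yi
                dfq[i, 2] = 0.5 * (1.0 + ci) * (1.0 - yi)
                dfq[i, 3] = 0.5 * (1.0 + ci) * yi
            tau = (1.0 - z[i]) / s[i]
            if tau < btau:
                btau = tau
                best = i
        if best < 0:
            break
        E = T + btau
        if E > t_max:
            break
        # dtau = -(dz_best + tau * ds_best) / s_best, ds = s * (dfc e_b + dfq)
        for m in range(p):
            dtau[m] = -dz[best, m] / s[best]
        dtau[best] -= btau * dfc[best]
        for r in range(4):
            dtau[n + r] -= btau * dfq[best, r]
        # advance the still-growing regions
        for i in range(n):
            if seized[i] or i == best:
                continue
            for m in range(p):
                dz[i, m] += s[i] * dtau[m]
            dz[i, i] += s[i] * dfc[i] * btau
            for r in range(4):
                dz[i, n + r] += s[i] * dfq[i, r] * btau
            z[i] += s[i] * btau
        t[best] = E
        for m in range(p):
            dt[best, m] = dT[m] + dtau[m]
            dT[m] = dt[best, m]
        z[best] = 1.0
        seized[best] = True
        for i in range(n):
            y[i] += W[i, best]
        T = E
    return t, dt[:, :n], dt[:, n:]


@njit(cache=True)
def sim_dense(W, q, c, dt_step, t_max):
    """First-order fixed-step integration; independent oracle for sim_event.

    The Heaviside input is evaluated at the left endpoint of each step
    (explicit Euler); a region's onset is the first grid time with z >= 1.
    """
    n = c.shape[0]
    t = np.full(n, np.inf)
    z = np.zeros(n)
    y = np.zeros(n)
    seized = np.zeros(n, np.bool_)
    n_steps = int(np.ceil(t_max / dt_step))
    remaining = n
    for k in range(n_steps):
        if remaining == 0:
            break
        for i in range(n):
            if seized[i]:
                continue
            f = _fhat(q[0], q[1], q[2], q[3], c[i], y[i])
            if f > _FCLIP:
                f = _FCLIP
            elif f < -_FCLIP:
                f = -_FCLIP
            z[i] += np.exp(f) * dt_step
        T = (k + 1) * dt_step
        for i in range(n):
            if not seized[i] and z[i] >= 1.0:
                t[i] = T
                seized[i] = True
                remaining -= 1
                for j in range(n):
                    y[j] += W[j, i]
    return t


_LOG_2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def logp_single(W, q, c, seiz_idx, seiz_t, nonseiz_idx, sigma_t, t_lim):
    """Single-seizure log posterior (standard-normal prior on c included)."""
    n = c.shape[0]
    lp = 0.0
    for i in range(n):
        lp += -0.5 * c[i] * c[i] - 0.5 * _LOG_2PI
    t = sim_event(W, q, c, t_lim)
    lognorm = -np.log(sigma_t) - 0.5 * _LOG_2PI
    inv2s2 = 0.5 / (sigma_t * sigma_t)
    for k in range(seiz_idx.shape[0]):
        i = seiz_idx[k]
        m = t[i] if t[i] < t_lim else t_lim
        r = seiz_t[k] - m
        lp += lognorm - r * r * inv2s2
    for k in range(nonseiz_idx.shape[0]):
        i = nonseiz_idx[k]
        m = t[i] if t[i] < t_lim else t_lim
        r = t_lim - m
        lp += lognorm - r * r * inv2s2
    return lp


@njit(cache=True)
def logp_grad_single(W, q, c, seiz_idx, seiz_t, nonseiz_idx, sigma_t, t_lim):
    """Log posterior with gradients w.r.t. c (length n) and raw q (length 4).

    Non-seizing terms use the printed one-sided form N(t_lim | min(t, t_lim),
    sigma_t): once the simulated onset passes t_lim the term saturates at its
    maximum and its gradient vanishes.
    """
    n = c.shape[0]
    lp = 0.0
    gc = np.zeros(n)
    gq = np.zeros(4)
    for i in range(n):
        lp += -0.5 * c[i] * c[i] - 0.5 * _LOG_2PI
        gc[i] = -c[i]
    t, dtdc, dtdq = sim_event_grad(W, q, c, t_lim)
    lognorm = -np.log(sigma_t) - 0.5 * _LOG_2PI
    inv_s2 = 1.0 / (sigma_t * sigma_t)
    for k in range(seiz_idx.shape[0]):
        i = seiz_idx[k]
        if t[i] < t_lim:
            r = seiz_t[k] - t[i]
            lp += lognorm - 0.5 * r * r * inv_s2
            coef = r * inv_s2  # d lp / d t_i
            for j in range(n):
                gc[j] += coef * dtdc[i, j]
            for rr in range(4):
                gq[rr] += coef * dtdq[i, rr]
        else:
            r = seiz_t[k] - t_lim
            lp += lognorm - 0.5 * r * r * inv_s2
    for k in range(nonseiz_idx.shape[0]):
        i = nonseiz_idx[k]
        if t[i] < t_lim:
            r = t_lim - t[i]
            lp += lognorm - 0.5 * r * r * inv_s2
            coef = r * inv_s2
            for j in range(n):
                gc[j] += coef * dtdc[i, j]
            for rr in range(4):
                gq[rr] += coef * dtdq[i, rr]
        else:
            lp += lognorm
    return lp, gc, gq


@njit(cache=True)
def logp_grad_cohort(
    Ws, q, C, s_idx, s_t, s_ptr, ns_idx, ns_ptr, sigma_t, t_lim
):
    """Sum of per-seizure log posteriors with gradients; seizure k's observed
    indices live in the CSR-style slices [s_ptr[k], s_ptr[k+1])."""
    K, n = C.shape
    lp = 0.0
    gC = np.zeros((K, n))
    gq = np.zeros(4)
    for k in range(K):
        lpk, gc, gqk = logp_grad_single(
            Ws[k], q, C[k],
            s_idx[s_ptr[k] : s_ptr[k + 1]],
            s_t[s_ptr[k] : s_ptr[k + 1]],
            ns_idx[ns_ptr[k] : ns_ptr[k + 1]],
            sigma_t, t_lim,
        )
        lp += lpk
        gC[k] = gc
        for r in range(4):
            gq[r] += gqk[r]
    return lp, gC, gq


@njit(cache=True)
def sim_event_batch(W, q, C, t_max):
    """Simulate one network under many excitability draws: C is (N, n)."""
    N, n = C.shape
    out = np.empty((N, n))
    for s in range(N):
        out[s] = sim_event(W, q, C[s], t_max)
    return out
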