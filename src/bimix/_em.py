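"""Compiled 1-D Gaussian-mixture EM kernel.

The two-component fit runs several deterministic restarts (quantile splits
plus the optimal 1-D two-means split) and keeps the restart with the
highest log-likelihood.  The kernel also tracks whether the log-likelihood
was non-decreasing across iterations, which the caller asserts: EM must be
monotone up to floating-point slack.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_2PI = 1.8378770664093453


@njit(cache=True)
def _loglik_k1(x: np.ndarray, mu: float, var: float) -> float:
    n = x.shape[0]
    s = 0.0
    for i in range(n):
        d = x[i] - mu
        s += d * d
    return -0.5 * n * (_LOG_2PI + np.log(var)) - 0.5 * s / var


@njit(cache=True)
def _em_k2_restarts(
    x: np.ndarray,
    mu_init: np.ndarray,   # (R, 2)
    var_init: np.ndarray,  # (R, 2)
    pi_init: np.ndarray,   # (R,)
    var_floor: float,
    tol: float,
    max_iter: int,
    equal_var: bool,
):
    """Run EM from each init; return best (mu1, mu2, var1, var2, pi1, ll, mono_ok)."""
    n = x.shape[0]
    R = mu_init.shape[0]
    best_ll = -np.inf
    best = (0.0, 0.0, var_floor, var_floor, 0.5)
    mono_ok = True
    resp = np.empty(n)
    for r in range(R):
        mu1 = mu_init[r, 0]
        mu2 = mu_init[r, 1]
        if equal_var:
            v0 = max(0.5 * (var_init[r, 0] + var_init[r, 1]), var_floor)
            v1 = v0
            v2 = v0
        else:
            v1 = max(var_init[r, 0], var_floor)
            v2 = max(var_init[r, 1], var_floor)
        p1 = min(max(pi_init[r], 1e-6), 1.0 - 1e-6)
        prev_ll = -np.inf
        ll = -np.inf
        for _ in range(max_iter):
            # E step (log-space per point for stability)
            lp1 = np.log(p1)
            lp2 = np.log(1.0 - p1)
            c1 = -0.5 * (_LOG_2PI + np.log(v1))
            c2 = -0.5 * (_LOG_2PI + np.log(v2))
            ll = 0.0
            s_r = 0.0
            for i in range(n):
                d1 = x[i] - mu1
                d2 = x[i] - mu2
                la = lp1 + c1 - 0.5 * d1 * d1 / v1
                lb = lp2 + c2 - 0.5 * d2 * d2 / v2
                m = la if la > lb else lb
                z = np.exp(la - m) + np.exp(lb - m)
                ll += m + np.log(z)
                ri = np.exp(la - m) / z
                resp[i] = ri
                s_r += ri
            if ll + 1e-6 * (1.0 + abs(ll)) < prev_ll:
                mono_ok = False
            if ll - prev_ll < tol and prev_ll > -np.inf:
                break
            prev_ll = ll
            # M step
            if s_r < 1e-10 or n - s_r < 1e-10:
                break  # one component emptied out; keep last params
            m1 = 0.0
            m2 = 0.0
            for i in range(n):
                m1 += resp[i] * x[i]
                m2 += (1.0 - resp[i]) * x[i]
            mu1 = m1 / s_r
            mu2 = m2 / (n - s_r)
            s1 = 0.0
            s2 = 0.0
            for i in range(n):
                d1 = x[i] - mu1
                d2 = x[i] - mu2
                s1 += resp[i] * d1 * d1
                s2 += (1.0 - resp[i]) * d2 * d2
            if equal_var:
                v = max((s1 + s2) / n, var_floor)
                v1 = v
                v2 = v
            else:
                v1 = max(s1 / s_r, var_floor)
                v2 = max(s2 / (n - s_r), var_floor)
            p1 = s_r / n
        if ll > best_ll:
            best_ll = ll
            best = (mu1, mu2, v1, v2, p1)
    mu1, mu2, v1, v2, p1 = best
    if mu1 > mu2:  # order components by mean
        mu1, mu2 = mu2, mu1
        v1, v2 = v2, v1
        p1 = 1.0 - p1
    return mu1, mu2, v1, v2, p1, best_ll, mono_ok


@njit(cache=True)
def _posterior_k2(x, mu1, mu2, v1, v2, p1):
    """Hard component assignment (0 = lower-mean component)."""
    n = x.shape[0]
    out = np.empty(n, dtype=np.int64)
    lp1 = np.log(p1) - 0.5 * np.log(v1)
    lp2 = np.log(1.0 - p1) - 0.5 * np.log(v2)
    for i in range(n):
        d1 = x[i] - mu1
        d2 = x[i] - mu2
        la = lp1 - 0.5 * d1 * d1 / v1
        lb = lp2 - 0.5 * d2 * d2 / v2
        out[i] = 0 if la >= lb else 1
    return out


def warmup() -> None:
    """Trigger JIT compilation on a tiny vector (optional convenience)."""
    x = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2, 0.3, 5.3, 0.4, 5.4])
    mu = np.array([[0.0, 5.0]])
    var = np.array([[1.0, 1.0]])
    pi = np.array([0.5])
    _em_k2_restarts(x, mu, var, pi, 1e-6, 1e-8, 10, True)
    _em_k2_restarts(x, mu, var, pi, 1e-6, 1e-8, 10, False)
    _posterior_k2(x, 0.0, 5.0, 1.0, 1.0, 0.5)
    _loglik_k1(x, 2.0, 1.0)
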