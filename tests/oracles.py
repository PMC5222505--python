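"""Independent brute-force oracles used to check the estimators.

Everything here is deliberately written as direct, unoptimized sums over
the defining formulas — no shared code with the package beyond numpy —
so agreement with the library is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def _as_td(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    return s[:, None] if s.ndim == 1 else s


def window_vector(s, t, tau) -> np.ndarray:
    """Lagged stimulus window at 0-based bin ``t``: entry d*L+i = s[t-i, d]."""
    s = _as_td(s)
    L = tau + 1
    return np.concatenate([[s[t - i, d] for i in range(L)] for d in range(s.shape[1])])


def brute_force_rwc(s, r, tau, demean=False) -> np.ndarray:
    """Response-weighted covariance by quintuple loop over (d1,i,d2,j,t)."""
    s = _as_td(s)
    T, D = s.shape
    L = tau + 1
    r = np.asarray(r, dtype=float).copy()
    if demean:
        r = r - r[tau:].mean()
    C = np.zeros((D * L, D * L))
    for d1 in range(D):
        for i in range(L):
            for d2 in range(D):
                for j in range(L):
                    acc = 0.0
                    for t in range(tau, T):
                        acc += r[t] * s[t - i, d1] * s[t - j, d2]
                    C[d1 * L + i, d2 * L + j] = acc / (T - tau)
    return C


def brute_force_sta(s, r, tau) -> tuple[np.ndarray, float]:
    s = _as_td(s)
    T = s.shape[0]
    r = np.asarray(r, dtype=float)
    n_r = r[tau:].sum()
    a = np.zeros((tau + 1) * s.shape[1])
    for t in range(tau, T):
        a += r[t] * window_vector(s, t, tau)
    return a / n_r, float(n_r)


def definitional_c1(s, r, tau) -> np.ndarray:
    """C1 from its pre-simplification form: mean of r_t (x_t - a)(x_t - a)^T
    over spikes, minus the plain stimulus covariance."""
    s = _as_td(s)
    T = s.shape[0]
    r = np.asarray(r, dtype=float)
    a, n_r = brute_force_sta(s, r, tau)
    acc = np.zeros((a.size, a.size))
    S = np.zeros_like(acc)
    for t in range(tau, T):
        x = window_vector(s, t, tau)
        acc += r[t] * np.outer(x - a, x - a)
        S += np.outer(x, x)
    return acc / n_r - S / (T - tau)


def definitional_c2(s, r, tau) -> np.ndarray:
    """C2 from its two-term form: subtract b_t = a (a.x_t)/(a.a) from every
    window, then take weighted minus unweighted covariance of the residuals."""
    s = _as_td(s)
    T = s.shape[0]
    r = np.asarray(r, dtype=float)
    a, n_r = brute_force_sta(s, r, tau)
    nrm2 = a @ a
    acc = np.zeros((a.size, a.size))
    unw = np.zeros_like(acc)
    for t in range(tau, T):
        x = window_vector(s, t, tau)
        y = x - a * (a @ x) / nrm2
        acc += r[t] * np.outer(y, y)
        unw += np.outer(y, y)
    return acc / n_r - unw / (T - tau)
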