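"""Minimal epsilon-SVR solver for tiny problems (QC series of ~10-20 points).

Solves the RBF-kernel epsilon-insensitive support vector regression dual

    min_beta  1/2 beta' K beta - y' beta + eps * ||beta||_1
    s.t.      sum(beta) = 0,  -C <= beta_i <= C

by pairwise coordinate (SMO-style) updates with maximal-violating-pair
selection; the prediction is f(x) = sum_i beta_i k(x, x_i) + b.  This is
the same optimization problem LIBSVM solves (beta_i = alpha_i - alpha_i*),
and agreement with :class:`sklearn.svm.SVR` is asserted by the test suite.
A hand-rolled solver is used because the drift-correction stage performs
hundreds of thousands of leave-one-out fits on ~12-point problems, where
estimator-framework overhead dominates runtime.  Compiled with numba when
available; falls back to pure Python.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def _smo_solve(K, y, C, eps, tol, max_iter):
    """Solve the epsilon-SVR dual; returns (beta, b, n_iter)."""
    n = y.shape[0]
    beta = np.zeros(n)
    g = -y.copy()  # gradient of the smooth part: K beta - y
    zero_tol = 1e-9 * (C if C > 1.0 else 1.0)
    it = 0
    while it < max_iter:
        it += 1
        # directional derivatives: up_i along +e_i, dn_i along -e_i
        up_best = np.inf
        up_second = np.inf
        i_best = -1
        i_second = -1
        dn_best = np.inf
        dn_second = np.inf
        j_best = -1
        j_second = -1
        for i in range(n):
            bi = beta[i]
            if bi < C - zero_tol:
                d = g[i] + (eps if bi >= -zero_tol else -eps)
                if d < up_best:
                    up_second = up_best
                    i_second = i_best
                    up_best = d
                    i_best = i
                elif d < up_second:
                    up_second = d
                    i_second = i
            if bi > -C + zero_tol:
                d = -g[i] + (eps if bi <= zero_tol else -eps)
                if d < dn_best:
                    dn_second = dn_best
                    j_second = j_best
                    dn_best = d
                    j_best = i
                elif d < dn_second:
                    dn_second = d
                    j_second = i
        # moving the same coordinate up and down cancels; use second bests
        if i_best == j_best:
            alt1 = up_best + dn_second if j_second >= 0 else np.inf
            alt2 = up_second + dn_best if i_second >= 0 else np.inf
            if alt1 <= alt2:
                j_sel = j_second
                i_sel = i_best
                total = alt1
            else:
                i_sel = i_second
                j_sel = j_best
                total = alt2
        else:
            i_sel = i_best
            j_sel = j_best
            total = up_best + dn_best
        if i_sel < 0 or j_sel < 0 or total >= -tol:
            break
        i = i_sel
        j = j_sel
        q = K[i, i] + K[j, j] - 2.0 * K[i, j]
        dmax = min(C - beta[i], beta[j] + C)
        if dmax <= 0.0:
            break
        # breakpoints of the piecewise-quadratic line search (|.|_1 kinks)
        t1 = -beta[i] if beta[i] < 0.0 else -1.0
        t2 = beta[j] if beta[j] > 0.0 else -1.0
        bp0 = dmax
        bp1 = dmax
        if 0.0 < t1 < dmax and 0.0 < t2 < dmax:
            bp0 = min(t1, t2)
            bp1 = max(t1, t2)
        elif 0.0 < t1 < dmax:
            bp0 = t1
        elif 0.0 < t2 < dmax:
            bp0 = t2
        g0 = g[i] - g[j]
        delta = dmax
        a = 0.0
        for seg in range(3):
            if seg == 0:
                b_end = bp0
            elif seg == 1:
                b_end = bp1
            else:
                b_end = dmax
            if b_end <= a:
                continue
            mid = 0.5 * (a + b_end)
            si = 1.0 if beta[i] + mid >= 0.0 else -1.0
            sj = 1.0 if beta[j] - mid >= 0.0 else -1.0
            const = g0 + eps * si - eps * sj
            slope_a = q * a + const
            if slope_a >= 0.0:
                delta = a
                break
            slope_b = q * b_end + const
            if slope_b < 0.0:
                a = b_end
                delta = b_end
                continue
            if q > 0.0:
                d = -const / q
                if d < a:
                    d = a
                elif d > b_end:
                    d = b_end
                delta = d
            else:
                delta = b_end
            break
        if delta <= 1e-14:
            break
        beta[i] += delta
        beta[j] -= delta
        for t in range(n):
            g[t] += delta * (K[t, i] - K[t, j])

    # intercept from the KKT multiplier interval (b = -lambda)
    lo = -np.inf
    hi = np.inf
    for i in range(n):
        bi = beta[i]
        if bi >= C - zero_tol:
            v = g[i] + eps
            if v > lo:
                lo = v
        elif bi > zero_tol:
            v = g[i] + eps
            if v > lo:
                lo = v
            if v < hi:
                hi = v
        elif bi >= -zero_tol:
            v = g[i] - eps
            if v > lo:
                lo = v
            v = g[i] + eps
            if v < hi:
                hi = v
        elif bi > -C + zero_tol:
            v = g[i] - eps
            if v > lo:
                lo = v
            if v < hi:
                hi = v
        else:
            v = g[i] - eps
            if v < hi:
                hi = v
    if not np.isfinite(lo):
        lam = hi
    elif not np.isfinite(hi):
        lam = lo
    else:
        lam = 0.5 * (lo + hi)
    return beta, -lam, it


@njit(cache=True)
def _loo_rmse_grid(Kg, y, eps_grid, C, tol, max_iter):
    """Leave-one-out RMSE for every (epsilon, gamma) grid combination.

    ``Kg`` holds one precomputed n x n RBF Gram matrix per gamma value.
    Returns an (n_eps, n_gamma) RMSE matrix.
    """
    G = Kg.shape[0]
    n = y.shape[0]
    E = eps_grid.shape[0]
    rmse = np.empty((E, G))
    Ks = np.empty((n - 1, n - 1))
    ys = np.empty(n - 1)
    idx = np.empty(n - 1, np.int64)
    for gi in range(G):
        for ei in range(E):
            sse = 0.0
            for leave in range(n):
                m = 0
                for t in range(n):
                    if t != leave:
                        idx[m] = t
                        m += 1
                for a in range(n - 1):
                    ys[a] = y[idx[a]]
                    for b in range(n - 1):
                        Ks[a, b] = Kg[gi, idx[a], idx[b]]
                beta, b0, _ = _smo_solve(Ks, ys, C, eps_grid[ei], tol, max_iter)
                pred = b0
                for a in range(n - 1):
                    pred += beta[a] * Kg[gi, leave, idx[a]]
                d = pred - y[leave]
                sse += d * d
            rmse[ei, gi] = np.sqrt(sse / n)
    return rmse


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, gamma: float) -> np.ndarray:
    d = x1[:, None] - x2[None, :]
    return np.exp(-gamma * d * d)


def solve_svr(x: np.ndarray, y: np.ndarray, gamma: float, epsilon: float, C: float,
              tol: float = 1e-3, max_iter: int = 100000):
    """Fit epsilon-SVR with an RBF kernel on 1-D inputs.

    Returns ``(beta, b)``; predict with
    ``rbf_kernel(x_new, x, gamma) @ beta + b``.
    """
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    K = rbf_kernel(x, x, gamma)
    beta, b, _ = _smo_solve(K, y, float(C), float(epsilon), float(tol), max_iter)
    return beta, b
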