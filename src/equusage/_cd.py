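"""Cyclic coordinate-descent kernels for the elastic net (numba-compiled).

The objective is the glmnet-style penalized least squares

    (1/2n) * sum_i (y_i - x_i.w)^2  +  lam * (alpha*||w||_1 + (1-alpha)/2*||w||_2^2)

solved by soft-threshold coordinate updates. The path solver uses warm
starts plus sequential strong-rule screening: candidate coordinates come
from the gradient at the previous lambda, descent runs on that working set
only, and a full KKT pass (one BLAS mat-vec) admits any violators before
moving on. Arrays are expected Fortran-ordered so column access is
contiguous.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def _sweep(X, r, w, cnorm, alpha, lam, idx, active_only):
    """One coordinate sweep over ``idx``; returns max coefficient change."""
    n = X.shape[0]
    max_change = 0.0
    for t in range(idx.size):
        j = idx[t]
        cj = cnorm[j]
        if cj <= 0.0:
            continue
        wj = w[j]
        if active_only and wj == 0.0:
            continue
        dot = 0.0
        for i in range(n):
            dot += X[i, j] * r[i]
        rho = dot / n + cj * wj
        z = abs(rho) - lam * alpha
        if z <= 0.0:
            w_new = 0.0
        else:
            w_new = np.sign(rho) * z / (cj + lam * (1.0 - alpha))
        d = w_new - wj
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            w[j] = w_new
            if abs(d) > max_change:
                max_change = abs(d)
    return max_change


@nb.njit(cache=True)
def _objective(r, w, alpha, lam, n):
    sse = 0.0
    for i in range(r.size):
        sse += r[i] * r[i]
    l1 = 0.0
    l2 = 0.0
    for j in range(w.size):
        l1 += abs(w[j])
        l2 += w[j] * w[j]
    return sse / (2.0 * n) + lam * (alpha * l1 + (1.0 - alpha) / 2.0 * l2)


@nb.njit(cache=True)
def _cd_on_set(X, r, w, cnorm, alpha, lam, idx, tol, max_iter, obj_trace, it0):
    """Descend to tolerance on the coordinates in ``idx`` (residual in place)."""
    n = X.shape[0]
    record = obj_trace.size > 0
    it = it0
    while it < max_iter:
        change = _sweep(X, r, w, cnorm, alpha, lam, idx, False)
        if record:
            obj_trace[it] = _objective(r, w, alpha, lam, n)
        it += 1
        if change < tol:
            break
        while it < max_iter:
            change = _sweep(X, r, w, cnorm, alpha, lam, idx, True)
            if record:
                obj_trace[it] = _objective(r, w, alpha, lam, n)
            it += 1
            if change < tol:
                break
    return it


@nb.njit(cache=True)
def cd_solve(X, y, alpha, lam, w, cnorm, tol, max_iter, obj_trace):
    """Solve one elastic-net problem in place; returns the sweep count.

    ``w`` is both warm start and output. ``obj_trace`` (len >= max_iter, or
    empty to skip) records the objective after every sweep; coordinate
    minimization makes it non-increasing.
    """
    p = X.shape[1]
    r = y - np.dot(X, w)
    idx = np.arange(p)
    return _cd_on_set(X, r, w, cnorm, alpha, lam, idx, tol, max_iter, obj_trace, 0)


@nb.njit(cache=True)
def cd_path(X, y, alpha, lams, cnorm, tol, max_iter):
    """Warm-started solutions along a decreasing lambda path (rows of W).

    Coordinates are screened per lambda with the sequential strong rule
    |g_j(lam_prev)| >= alpha*(2*lam_k - lam_prev); after convergence on the
    working set a full KKT check admits any violators (so the screen never
    changes the solution, only the work).
    """
    n, p = X.shape
    L = lams.size
    W = np.zeros((L, p))
    w = np.zeros(p)
    r = y.copy()
    empty = np.empty(0)
    in_set = np.zeros(p, dtype=nb.boolean)
    lam_prev = lams[0]
    for k in range(L):
        lam = lams[k]
        g = np.dot(r, X) / n
        if alpha > 0.0:
            thresh = alpha * max(2.0 * lam - lam_prev, lam)
        else:
            thresh = -1.0  # ridge: no safe screen, take everything
        for j in range(p):
            in_set[j] = w[j] != 0.0 or abs(g[j]) >= thresh
        while True:
            idx = np.nonzero(in_set)[0]
            _cd_on_set(X, r, w, cnorm, alpha, lam, idx, tol, max_iter, empty, 0)
            g = np.dot(r, X) / n
            grew = False
            slack = lam * alpha + max(tol, 1e-12)
            for j in range(p):
                if not in_set[j] and cnorm[j] > 0.0 and abs(g[j]) > slack:
                    in_set[j] = True
                    grew = True
            if not grew:
                break
        W[k, :] = w
        lam_prev = lam
    return W


def kkt_residual(X, y, w, alpha, lam, cnorm=None) -> float:
    """Max violation of the stationarity conditions (0 at the exact optimum)."""
    X = np.asarray(X, float)
    n = X.shape[0]
    if cnorm is None:
        cnorm = np.einsum("ij,ij->j", X, X) / n
    g = X.T @ (y - X @ w) / n  # (1/n) X^T r
    resid = np.zeros_like(w)
    nz = w != 0
    resid[nz] = np.abs(g[nz] - lam * (1 - alpha) * w[nz] - lam * alpha * np.sign(w[nz]))
    resid[~nz] = np.maximum(np.abs(g[~nz]) - lam * alpha, 0.0)
    resid[cnorm <= 0] = 0.0
    return float(np.max(resid)) if resid.size else 0.0
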