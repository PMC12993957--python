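"""Numba inner loops for archetypal (simplex) fitting.

These kernels are deliberately minimal and allocation-free in the hot loops
(k is at most 7, so per-row work uses small fixed buffers and insertion
sort). The public fitting API, input validation, restarts and the expansion
step live in :mod:`paretocell.polytope_fit`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _project_row_simplex(buf, k, out_row):
    """Euclidean projection of buf[:k] onto the probability simplex -> out_row."""
    # insertion sort descending into a local copy
    u = np.empty(k)
    for j in range(k):
        u[j] = buf[j]
    for a in range(1, k):
        key = u[a]
        b = a - 1
        while b >= 0 and u[b] < key:
            u[b + 1] = u[b]
            b -= 1
        u[b + 1] = key
    css = 0.0
    theta = 0.0
    for j in range(k):
        css += u[j]
        t = (css - 1.0) / (j + 1)
        if u[j] - t > 0.0:
            theta = t
    for j in range(k):
        v = buf[j] - theta
        out_row[j] = v if v > 0.0 else 0.0


@njit(cache=True)
def _update_weights(X, V, W, n_iter):
    """Projected-gradient steps for min ||X - W V||^2 with rows of W on the simplex."""
    n, d = X.shape
    k = V.shape[0]
    VVt = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            s = 0.0
            for c in range(d):
                s += V[a, c] * V[b, c]
            VVt[a, b] = s
    XVt = np.empty((n, k))
    for i in range(n):
        for j in range(k):
            s = 0.0
            for c in range(d):
                s += X[i, c] * V[j, c]
            XVt[i, j] = s
    # infinity-norm bound on the largest eigenvalue of VVt -> safe step size
    L = 0.0
    for a in range(k):
        s = 0.0
        for b in range(k):
            s += abs(VVt[a, b])
        if s > L:
            L = s
    if L <= 0.0:
        return
    step = 1.0 / L
    buf = np.empty(k)
    for _ in range(n_iter):
        for i in range(n):
            for j in range(k):
                g = -XVt[i, j]
                for l in range(k):
                    g += W[i, l] * VVt[l, j]
                buf[j] = W[i, j] - step * g
            _project_row_simplex(buf, k, W[i])


@njit(cache=True)
def _project_long_row_simplex(row):
    """In-place Euclidean projection of an arbitrary-length vector onto the simplex."""
    n = row.shape[0]
    u = np.sort(row)[::-1]
    css = 0.0
    theta = 0.0
    for j in range(n):
        css += u[j]
        t = (css - 1.0) / (j + 1)
        if u[j] - t > 0.0:
            theta = t
    for j in range(n):
        v = row[j] - theta
        row[j] = v if v > 0.0 else 0.0


@njit(cache=True)
def _inf_norm(M):
    L = 0.0
    for a in range(M.shape[0]):
        s = 0.0
        for b in range(M.shape[1]):
            s += abs(M[a, b])
        if s > L:
            L = s
    return L


@njit(cache=True)
def _aa_fit(X, Xb, init_idx, k, w_iters, b_iters, max_outer, tol):
    """Principal-convex-hull alternating optimization.

    Archetypes are convex combinations of basis points (V = B Xb, rows of B
    on the simplex), which keeps the fitted polytope within the data and
    makes the objective well-posed; per-cell weights W are
    simplex-constrained. The basis Xb is typically the convex-hull vertices
    of X — a lossless restriction, since conv(X) = conv(hull vertices) —
    and ``init_idx`` indexes into it. Both factors are updated by projected
    gradient. Returns (V, W, sse).
    """
    n, d = X.shape
    m = Xb.shape[0]
    B = np.zeros((k, m))
    for j in range(k):
        B[j, init_idx[j]] = 1.0
    V = B @ Xb
    W = np.full((n, k), 1.0 / k)
    XbtXb = Xb @ Xb.T  # m x m is small (hull vertices)
    Lx = _inf_norm(XbtXb)
    prev = 1.0e300
    sse = prev
    for _ in range(max_outer):
        _update_weights(X, V, W, w_iters)
        WtW = W.T @ W
        WtX = W.T @ X
        Lw = _inf_norm(WtW)
        if Lw * Lx > 0.0:
            step = 1.0 / (Lw * Lx)
            for _it in range(b_iters):
                G = (WtW @ V - WtX) @ Xb.T  # k x m
                B -= step * G
                for j in range(k):
                    _project_long_row_simplex(B[j])
                V = B @ Xb
        sse = 0.0
        for i in range(n):
            for c in range(d):
                r = X[i, c]
                for a in range(k):
                    r -= W[i, a] * V[a, c]
                sse += r * r
        if prev - sse < tol * (prev + 1e-300):
            break
        prev = sse
    return V, W, sse


@njit(cache=True)
def _furthest_point_indices(X, k, first):
    """Greedy furthest-point selection of k data indices, starting at `first`."""
    n = X.shape[0]
    d = X.shape[1]
    idx = np.empty(k, np.int64)
    idx[0] = first
    mind = np.full(n, 1.0e300)
    for j in range(1, k):
        p = X[idx[j - 1]]
        best = 0
        bv = -1.0
        for i in range(n):
            s = 0.0
            for b in range(d):
                t = X[i, b] - p[b]
                s += t * t
            if s < mind[i]:
                mind[i] = s
            if mind[i] > bv:
                bv = mind[i]
                best = i
        idx[j] = best
    return idx
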