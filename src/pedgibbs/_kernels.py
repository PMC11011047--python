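"""Numba kernels for the Gibbs sweep over location effects.

All randomness is injected as pre-drawn standard-normal arrays so the
kernels are deterministic; the caller owns the seeded generator.  The
residual matrix ``e`` is updated in place and always equals
``y - Xb - Zu - Wpe`` on exit.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _solve_lower(L, b):
    t = L.shape[0]
    x = np.empty(t)
    for i in range(t):
        s = b[i]
        for j in range(i):
            s -= L[i, j] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _solve_upper_t(L, b):
    # solves L.T x = b for lower-triangular L
    t = L.shape[0]
    x = np.empty(t)
    for i in range(t - 1, -1, -1):
        s = b[i]
        for j in range(i + 1, t):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def update_fixed(e, col_indptr, col_rows, col_vals, col_sq, b, Le, z):
    """Gibbs update of every fixed-effect coefficient vector.

    ``X`` is passed column-wise (CSC-style).  With a flat prior, the full
    conditional of column ``j`` is Gaussian with mean ``r / sum(x^2)`` and
    covariance ``Sigma_e / sum(x^2)`` where ``r`` accumulates
    ``x' (e + x b_j)`` per trait.
    """
    f, t = b.shape
    for j in range(f):
        sjj = col_sq[j]
        if sjj <= 0.0:
            continue
        r = np.zeros(t)
        for ptr in range(col_indptr[j], col_indptr[j + 1]):
            i = col_rows[ptr]
            v = col_vals[ptr]
            for k in range(t):
                r[k] += v * e[i, k]
        for k in range(t):
            r[k] = r[k] / sjj + b[j, k]
        scale = 1.0 / np.sqrt(sjj)
        new = np.empty(t)
        for k in range(t):
            s = 0.0
            for m in range(k + 1):
                s += Le[k, m] * z[j, m]
            new[k] = r[k] + scale * s
        for ptr in range(col_indptr[j], col_indptr[j + 1]):
            i = col_rows[ptr]
            v = col_vals[ptr]
            for k in range(t):
                e[i, k] -= v * (new[k] - b[j, k])
        for k in range(t):
            b[j, k] = new[k]


@njit(cache=True)
def update_random(
    e,
    eff,
    rec_indptr,
    rec_idx,
    g_indptr,
    g_indices,
    g_data,
    Se_inv,
    G_inv,
    z,
):
    """Single-site Gibbs update of one random-effect block.

    ``eff`` is (levels, traits); level ``i`` owns records
    ``rec_idx[rec_indptr[i]:rec_indptr[i+1]]``.  The prior precision
    graph (``A^{-1}`` for genetic effects, identity for iid permanent
    environment) comes in CSR form.  Full conditional per level:
    precision ``n_i Se_inv + g_ii G_inv`` and right-hand side
    ``Se_inv r_i - G_inv sum_{j!=i} g_ij eff_j``.
    """
    q, t = eff.shape
    for i in range(q):
        n_i = rec_indptr[i + 1] - rec_indptr[i]
        r = np.zeros(t)
        for ptr in range(rec_indptr[i], rec_indptr[i + 1]):
            rec = rec_idx[ptr]
            for k in range(t):
                r[k] += e[rec, k]
        for k in range(t):
            r[k] += n_i * eff[i, k]

        g = np.zeros(t)
        g_ii = 0.0
        for ptr in range(g_indptr[i], g_indptr[i + 1]):
            j = g_indices[ptr]
            v = g_data[ptr]
            if j == i:
                g_ii = v
            else:
                for k in range(t):
                    g[k] += v * eff[j, k]

        P = n_i * Se_inv + g_ii * G_inv
        rhs = np.empty(t)
        for k in range(t):
            s = 0.0
            for m in range(t):
                s += Se_inv[k, m] * r[m] - G_inv[k, m] * g[m]
            rhs[k] = s
        L = np.linalg.cholesky(P)
        mean = _solve_upper_t(L, _solve_lower(L, rhs))
        draw = _solve_upper_t(L, z[i])
        for k in range(t):
            new = mean[k] + draw[k]
            delta = new - eff[i, k]
            eff[i, k] = new
            for ptr in range(rec_indptr[i], rec_indptr[i + 1]):
                e[rec_idx[ptr], k] -= delta
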