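"""Numba kernels for the single-site Gibbs sweeps.

Each kernel performs one full sweep over its block of effects, updating
the residual vector in place.  All Gaussian noise is passed in as
pre-generated standard normals so that every source of randomness flows
from one seeded generator in the Python driver; given a seed, chains are
bit-for-bit reproducible.

The full conditional for a scalar effect u_j with prior N(0, s2u) in a
model with residual variance s2e is N(rhs / c, s2e / c) with
c = z_j'z_j + s2e/s2u and rhs = z_j'(e + z_j u_j).  For the correlated
multi-breed update the per-locus K-vector u_j has prior N(0, B) and full
conditional N(C^-1 r, s2e C^-1) with C = W_j + s2e B^-1, where
W_j[k, l] = z_jk' z_jl and r_k = z_jk' e + (W_j u_j)_k.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def sweep_fixed(Xt, xx, e, b, s2e, normals):
    """Coordinate Gibbs for fixed effects with flat priors.

    Xt is (p, n) with contiguous rows; xx holds the column sums of
    squares.  Updates b and the residual e in place.
    """
    p, n = Xt.shape
    for k in range(p):
        x = Xt[k]
        bk = b[k]
        rhs = 0.0
        for i in range(n):
            rhs += x[i] * (e[i] + x[i] * bk)
        c = xx[k]
        new = rhs / c + math.sqrt(s2e / c) * normals[k]
        d = new - bk
        for i in range(n):
            e[i] -= x[i] * d
        b[k] = new


@njit(cache=True, fastmath=True)
def sweep_effects_single(Zt, zz, e, u, lam, s2e, normals):
    """Single-site sweep over markers for one i.i.d.-prior effect block.

    Zt is (m, n); lam = s2e / s2u.  Updates u and e in place.
    """
    m, n = Zt.shape
    for j in range(m):
        z = Zt[j]
        uj = u[j]
        rhs = 0.0
        for i in range(n):
            rhs += z[i] * (e[i] + z[i] * uj)
        c = zz[j] + lam
        new = rhs / c + math.sqrt(s2e / c) * normals[j]
        d = new - uj
        for i in range(n):
            e[i] -= z[i] * d
        u[j] = new


@njit(cache=True, fastmath=True)
def _chol_small(A, L):
    """In-place Cholesky of a small SPD matrix; returns False on failure."""
    K = A.shape[0]
    for i in range(K):
        for j in range(i + 1):
            s = A[i, j]
            for t in range(j):
                s -= L[i, t] * L[j, t]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = math.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, K):
            L[i, j] = 0.0
    return True


@njit(cache=True, fastmath=True)
def sweep_effects_correlated(Zts, W, e, U, Binv, s2e, normals, work):
    """Per-locus joint update of the K-vector of breed effects.

    Zts is (K, m, n); W is (m, K, K) with the per-locus cross products
    z_jk' z_jl; U is (m, K); Binv is the inverse of the current B.  The
    draw uses C = W_j + s2e * Binv: mean solves C mean = r and the noise
    is sqrt(s2e) * L^-T z with C = L L'.  Returns the index of the first
    locus whose C failed to factor (or -1), so the driver can raise.
    """
    K, m, n = Zts.shape
    C = work[0]
    L = work[1]
    r = np.empty(K)
    yv = np.empty(K)
    x = np.empty(K)
    for j in range(m):
        for k in range(K):
            z = Zts[k, j]
            s = 0.0
            for i in range(n):
                s += z[i] * e[i]
            r[k] = s
        for k in range(K):
            s = r[k]
            for l in range(K):
                s += W[j, k, l] * U[j, l]
                C[k, l] = W[j, k, l] + s2e * Binv[k, l]
            yv[k] = s
        if not _chol_small(C, L):
            return j
        # solve C mean = yv via L y = yv ; L' mean = y
        for k in range(K):
            s = yv[k]
            for t in range(k):
                s -= L[k, t] * r[t]
            r[k] = s / L[k, k]
        for k in range(K - 1, -1, -1):
            s = r[k]
            for t in range(k + 1, K):
                s -= L[t, k] * x[t]
            x[k] = s / L[k, k]
        # noise: sqrt(s2e) * L^-T z  (back substitution on the normals)
        for k in range(K - 1, -1, -1):
            s = normals[j, k]
            for t in range(k + 1, K):
                s -= L[t, k] * yv[t]
            yv[k] = s / L[k, k]
        sq = math.sqrt(s2e)
        for k in range(K):
            x[k] = x[k] + sq * yv[k]
        for i in range(n):
            acc = 0.0
            for k in range(K):
                acc += Zts[k, j, i] * (x[k] - U[j, k])
            e[i] -= acc
        for k in range(K):
            U[j, k] = x[k]
    return -1
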