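"""Numba kernels for the two-state binomial HMM.

All recursions use scaled probabilities with per-site emission
renormalisation (subtracting the per-site max log emission), which keeps the
arithmetic in a well-conditioned range for arbitrary read depths while
recovering the exact log-likelihood from the scaling constants.
"""

from math import exp, lgamma, log

import numpy as np
from numba import njit


@njit(cache=True)
def _log_emissions(meth, total, p0, p1):
    n = meth.shape[0]
    lb = np.empty((n, 2))
    lp0, l1p0 = log(p0), log(1.0 - p0)
    lp1, l1p1 = log(p1), log(1.0 - p1)
    for i in range(n):
        m = meth[i]
        t = total[i]
        c = lgamma(t + 1.0) - lgamma(m + 1.0) - lgamma(t - m + 1.0)
        lb[i, 0] = c + m * lp0 + (t - m) * l1p0
        lb[i, 1] = c + m * lp1 + (t - m) * l1p1
    return lb


@njit(cache=True)
def _forward_scaled(lb, A, pi, alpha, scale):
    """Fill scaled forward variables; returns the log-likelihood."""
    n = lb.shape[0]
    ll = 0.0
    for i in range(n):
        m = lb[i, 0] if lb[i, 0] > lb[i, 1] else lb[i, 1]
        b0 = exp(lb[i, 0] - m)
        b1 = exp(lb[i, 1] - m)
        if i == 0:
            f0 = pi[0] * b0
            f1 = pi[1] * b1
        else:
            f0 = (alpha[i - 1, 0] * A[0, 0] + alpha[i - 1, 1] * A[1, 0]) * b0
            f1 = (alpha[i - 1, 0] * A[0, 1] + alpha[i - 1, 1] * A[1, 1]) * b1
        s = f0 + f1
        alpha[i, 0] = f0 / s
        alpha[i, 1] = f1 / s
        scale[i] = s
        ll += log(s) + m
    return ll


@njit(cache=True)
def forward_loglik(meth, total, p0, p1, A, pi):
    lb = _log_emissions(meth, total, p0, p1)
    n = lb.shape[0]
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    return _forward_scaled(lb, A, pi, alpha, scale)


@njit(cache=True)
def estep(meth, total, p0, p1, A, pi):
    """One E-step on a single sequence.

    Returns (ll, gamma0[2], gamma_sum[2], gamma_meth[2], gamma_total[2],
    xi[2,2]) where gamma_meth/total are posterior-weighted count sums used
    for the binomial M-step and xi the expected transition counts.
    """
    lb = _log_emissions(meth, total, p0, p1)
    n = lb.shape[0]
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    ll = _forward_scaled(lb, A, pi, alpha, scale)

    # normalized emissions re-derived for the backward pass
    b = np.empty((n, 2))
    for i in range(n):
        m = lb[i, 0] if lb[i, 0] > lb[i, 1] else lb[i, 1]
        b[i, 0] = exp(lb[i, 0] - m)
        b[i, 1] = exp(lb[i, 1] - m)

    gamma0 = np.zeros(2)
    gsum = np.zeros(2)
    gmeth = np.zeros(2)
    gtotal = np.zeros(2)
    xi = np.zeros((2, 2))

    beta0, beta1 = 1.0, 1.0
    for i in range(n - 1, -1, -1):
        g0 = alpha[i, 0] * beta0
        g1 = alpha[i, 1] * beta1
        z = g0 + g1
        g0 /= z
        g1 /= z
        gsum[0] += g0
        gsum[1] += g1
        gmeth[0] += g0 * meth[i]
        gmeth[1] += g1 * meth[i]
        gtotal[0] += g0 * total[i]
        gtotal[1] += g1 * total[i]
        if i == 0:
            gamma0[0] = g0
            gamma0[1] = g1
        if i > 0:
            # xi over the transition (i-1) -> i, using scaled quantities
            denom = scale[i]
            x00 = alpha[i - 1, 0] * A[0, 0] * b[i, 0] * beta0 / denom
            x01 = alpha[i - 1, 0] * A[0, 1] * b[i, 1] * beta1 / denom
            x10 = alpha[i - 1, 1] * A[1, 0] * b[i, 0] * beta0 / denom
            x11 = alpha[i - 1, 1] * A[1, 1] * b[i, 1] * beta1 / denom
            zx = x00 + x01 + x10 + x11
            xi[0, 0] += x00 / zx
            xi[0, 1] += x01 / zx
            xi[1, 0] += x10 / zx
            xi[1, 1] += x11 / zx
            nb0 = (A[0, 0] * b[i, 0] * beta0 + A[0, 1] * b[i, 1] * beta1) / denom
            nb1 = (A[1, 0] * b[i, 0] * beta0 + A[1, 1] * b[i, 1] * beta1) / denom
            beta0, beta1 = nb0, nb1
    return ll, gamma0, gsum, gmeth, gtotal, xi


@njit(cache=True)
def posteriors(meth, total, p0, p1, A, pi):
    """Full per-site posterior state probabilities (gamma)."""
    lb = _log_emissions(meth, total, p0, p1)
    n = lb.shape[0]
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    _forward_scaled(lb, A, pi, alpha, scale)
    b = np.empty((n, 2))
    for i in range(n):
        m = lb[i, 0] if lb[i, 0] > lb[i, 1] else lb[i, 1]
        b[i, 0] = exp(lb[i, 0] - m)
        b[i, 1] = exp(lb[i, 1] - m)
    gamma = np.empty((n, 2))
    beta0, beta1 = 1.0, 1.0
    for i in range(n - 1, -1, -1):
        g0 = alpha[i, 0] * beta0
        g1 = alpha[i, 1] * beta1
        z = g0 + g1
        gamma[i, 0] = g0 / z
        gamma[i, 1] = g1 / z
        if i > 0:
            denom = scale[i]
            nb0 = (A[0, 0] * b[i, 0] * beta0 + A[0, 1] * b[i, 1] * beta1) / denom
            nb1 = (A[1, 0] * b[i, 0] * beta0 + A[1, 1] * b[i, 1] * beta1) / denom
            beta0, beta1 = nb0, nb1
    return gamma


@njit(cache=True)
def viterbi(meth, total, p0, p1, A, pi):
    """Most probable state path (0/1 per site)."""
    lb = _log_emissions(meth, total, p0, p1)
    n = lb.shape[0]
    la = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            la[i, j] = log(A[i, j])
    back = np.empty((n, 2), dtype=np.int8)
    d0 = log(pi[0]) + lb[0, 0]
    d1 = log(pi[1]) + lb[0, 1]
    for i in range(1, n):
        c00 = d0 + la[0, 0]
        c10 = d1 + la[1, 0]
        if c00 >= c10:
            nd0 = c00 + lb[i, 0]
            back[i, 0] = 0
        else:
            nd0 = c10 + lb[i, 0]
            back[i, 0] = 1
        c01 = d0 + la[0, 1]
        c11 = d1 + la[1, 1]
        if c01 >= c11:
            nd1 = c01 + lb[i, 1]
            back[i, 1] = 0
        else:
            nd1 = c11 + lb[i, 1]
            back[i, 1] = 1
        d0, d1 = nd0, nd1
    path = np.empty(n, dtype=np.int8)
    path[n - 1] = 0 if d0 >= d1 else 1
    for i in range(n - 2, -1, -1):
        path[i] = back[i + 1, path[i + 1]]
    return path
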