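"""Jit-compiled hot loops for the sampler.

The sequential per-SNP field sweep and the whole-track mixture
log-likelihood dominate run time (they run once per MCMC iteration);
everything here is plain array arithmetic compiled with numba.  All random
draws are made by the caller and passed in, so the kernels are pure
functions of their inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG_HUGE = -1.0e308


@njit(cache=True)
def _logsumexp(v):
    m = _NEG_HUGE
    for a in range(v.shape[0]):
        if v[a] > m:
            m = v[a]
    s = 0.0
    for a in range(v.shape[0]):
        s += np.exp(v[a] - m)
    return m + np.log(s)


@njit(cache=True)
def total_log_mixture(x, act, y, mu_act, sigma2_act, phi):
    """sum_i log( sum_j w_ij N(y_i | mu_j, sigma2_j) ) over active classes.

    Weights are the tempered softmax of x[i, act], so per SNP the term is
    logsumexp(x/phi + logN) - logsumexp(x/phi).
    """
    n = y.shape[0]
    k = act.shape[0]
    logc = np.empty(k)
    inv2 = np.empty(k)
    for a in range(k):
        logc[a] = -0.5 * np.log(2.0 * np.pi * sigma2_act[a])
        inv2[a] = 0.5 / sigma2_act[a]
    v = np.empty(k)
    w = np.empty(k)
    total = 0.0
    for i in range(n):
        for a in range(k):
            d = y[i] - mu_act[a]
            w[a] = x[i, act[a]] / phi
            v[a] = w[a] + logc[a] - d * d * inv2[a]
        total += _logsumexp(v) - _logsumexp(w)
    return total


@njit(cache=True)
def pairwise_sq_diff(x, act, nb):
    """sum over active columns and unordered neighbor pairs of
    (x_ij - x_i'j)^2 for the window graph of half-width nb."""
    n = x.shape[0]
    s = 0.0
    for a in range(act.shape[0]):
        c = act[a]
        for i in range(n - 1):
            hi = i + nb
            if hi > n - 1:
                hi = n - 1
            for j in range(i + 1, hi + 1):
                d = x[i, c] - x[j, c]
                s += d * d
    return s


@njit(cache=True)
def sweep_field(x, act, y, mu_act, sigma2_act, h, phi, nb,
                norm_draws, unif_draws, data_on):
    """One sequential Metropolis-Hastings sweep over SNP locations.

    At each SNP i the whole active row (x_i,j1 .. x_i,jk) is proposed
    jointly from the product of the per-field full conditionals
    N(h * sum_nbrs x / (1 + h n_i), 1 / (1 + h n_i)); since the proposal is
    the exact prior full conditional, the acceptance probability reduces to
    the ratio of mixture densities at y_i.  With ``data_on`` false the
    proposal is always accepted (pure prior Gibbs sweep).  Mutates ``x``
    in place; returns the number of accepted locations.
    """
    n = x.shape[0]
    k = act.shape[0]
    logc = np.empty(k)
    inv2 = np.empty(k)
    for a in range(k):
        logc[a] = -0.5 * np.log(2.0 * np.pi * sigma2_act[a])
        inv2[a] = 0.5 / sigma2_act[a]
    xprop = np.empty(k)
    vo = np.empty(k)
    vn = np.empty(k)
    wo = np.empty(k)
    wn = np.empty(k)
    accepted = 0
    for i in range(n):
        lo = i - nb
        if lo < 0:
            lo = 0
        hi = i + nb
        if hi > n - 1:
            hi = n - 1
        n_i = hi - lo  # window size minus self
        var = 1.0 / (1.0 + h * n_i)
        sd = np.sqrt(var)
        for a in range(k):
            c = act[a]
            s = 0.0
            for j in range(lo, hi + 1):
                if j != i:
                    s += x[j, c]
            xprop[a] = h * s * var + sd * norm_draws[i, a]
        accept = True
        if data_on:
            for a in range(k):
                c = act[a]
                d = y[i] - mu_act[a]
                ll = logc[a] - d * d * inv2[a]
                wo[a] = x[i, c] / phi
                wn[a] = xprop[a] / phi
                vo[a] = wo[a] + ll
                vn[a] = wn[a] + ll
            log_acc = (_logsumexp(vn) - _logsumexp(wn)) \
                - (_logsumexp(vo) - _logsumexp(wo))
            accept = np.log(unif_draws[i]) < log_acc
        if accept:
            for a in range(k):
                x[i, act[a]] = xprop[a]
            accepted += 1
    return accepted
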