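"""Compiled inner loops for the MH-within-Gibbs sampler.

These kernels maintain the current distance matrix D, the covariate part of
the linear predictor C = beta0 + X beta, and a per-pair log-likelihood
cache L (L[i, j] = log P(y_ij | eta_ij), 0 on the diagonal), and perform
the per-node latent updates, per-coefficient regression updates and the
joint Dirichlet popularity move.  Caching L means each proposal costs one
fresh Bernoulli term per affected pair instead of two.  All kernels consume
numba's global RNG stream, seeded once per sampler run for
bit-reproducibility.

Everything here is an implementation detail of :mod:`phlsm.mcmc`; the
documented per-operation entry points live there.
"""

import math

import numpy as np
from numba import njit

# penalty codes for beta updates
RIDGE = 0
LASSO = 1


@njit(cache=True)
def seed_kernels(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def bern_ll(eta, y):
    """y*eta - log(1 + exp(eta)), overflow-safe."""
    if eta > 37.0:
        return (y - 1.0) * eta
    if eta < -37.0:
        return y * eta
    if eta > 0.0:
        return (y - 1.0) * eta - math.log1p(math.exp(-eta))
    return y * eta - math.log1p(math.exp(eta))


@njit(cache=True)
def fill_ll(C, D, gamma, Y, L):
    """Recompute the whole pair log-likelihood cache; returns its sum."""
    n = gamma.shape[0]
    total = 0.0
    for i in range(n):
        L[i, i] = 0.0
        for j in range(n):
            if i == j:
                continue
            v = bern_ll(C[i, j] - D[i, j] / gamma[j], Y[i, j])
            L[i, j] = v
            total += v
    return total


@njit(cache=True, inline="always")
def _mix_logprior(zi, d, weights, means, variances):
    G = weights.shape[0]
    best = -1.0e308
    comp = np.empty(G)
    for g in range(G):
        s = 0.0
        for t in range(d):
            diff = zi[t] - means[g, t]
            s += diff * diff
        v = variances[g]
        c = math.log(weights[g]) - 0.5 * d * math.log(2.0 * math.pi * v) - 0.5 * s / v
        comp[g] = c
        if c > best:
            best = c
    acc = 0.0
    for g in range(G):
        acc += math.exp(comp[g] - best)
    return best + math.log(acc)


@njit(cache=True)
def z_sweep(Z, D, C, gamma, Y, L, step, sigma2, mix_on, mixw, mixmu, mixvar,
            lik_w):
    """One MH random-walk pass over all latent positions.

    Updates Z, D and L in place; returns (accept count, accepted log-lik
    delta).
    """
    n, d = Z.shape
    acc = 0
    ll_delta = 0.0
    zi = np.empty(d)
    dnew = np.empty(n)
    ll_out = np.empty(n)
    ll_in = np.empty(n)
    for i in range(n):
        for t in range(d):
            zi[t] = Z[i, t] + step * np.random.normal()
        delta = 0.0
        for j in range(n):
            if j == i:
                continue
            s = 0.0
            for t in range(d):
                diff = zi[t] - Z[j, t]
                s += diff * diff
            dn = math.sqrt(s)
            dnew[j] = dn
            lo = bern_ll(C[i, j] - dn / gamma[j], Y[i, j])
            li = bern_ll(C[j, i] - dn / gamma[i], Y[j, i])
            ll_out[j] = lo
            ll_in[j] = li
            delta += lo - L[i, j] + li - L[j, i]
        ll_part = delta
        delta *= lik_w
        if mix_on:
            zold = Z[i]
            delta += _mix_logprior(zi, d, mixw, mixmu, mixvar) \
                - _mix_logprior(zold, d, mixw, mixmu, mixvar)
        else:
            so = 0.0
            sn = 0.0
            for t in range(d):
                sn += zi[t] * zi[t]
                so += Z[i, t] * Z[i, t]
            delta += -0.5 * (sn - so) / sigma2
        if math.log(np.random.random()) < delta:
            acc += 1
            ll_delta += ll_part
            for j in range(n):
                if j != i:
                    D[i, j] = dnew[j]
                    D[j, i] = dnew[j]
                    L[i, j] = ll_out[j]
                    L[j, i] = ll_in[j]
            for t in range(d):
                Z[i, t] = zi[t]
    return acc, ll_delta


@njit(cache=True)
def beta_sweep(beta, C, D, gamma, Y, L, offs, idx_i, idx_j, xval, scratch,
               step, acc_k, penalty, pen_par, lik_w):
    """One MH pass over regression coefficients (Normal walk for ridge,
    Laplace walk for lasso), with a per-coefficient step size.  Only pairs
    with x_ijk != 0 are visited; C and L are updated in place on
    acceptance; per-coefficient accept counts accumulate into ``acc_k``."""
    p = beta.shape[0]
    acc = 0
    ll_delta = 0.0
    for k in range(p):
        if penalty == RIDGE:
            db = step[k] * np.random.normal()
        else:
            db = step[k] * np.random.laplace()
        delta = 0.0
        for t in range(offs[k], offs[k + 1]):
            i = idx_i[t]
            j = idx_j[t]
            v = bern_ll(C[i, j] + db * xval[t] - D[i, j] / gamma[j], Y[i, j])
            scratch[t] = v
            delta += v - L[i, j]
        ll_part = delta
        delta *= lik_w
        bo = beta[k]
        bn = bo + db
        if penalty == RIDGE:
            delta += -0.5 * pen_par[k] * (bn * bn - bo * bo)
        else:
            delta += -pen_par[k] * (abs(bn) - abs(bo))
        if math.log(np.random.random()) < delta:
            acc += 1
            acc_k[k] += 1
            ll_delta += ll_part
            beta[k] = bn
            for t in range(offs[k], offs[k + 1]):
                i = idx_i[t]
                j = idx_j[t]
                C[i, j] += db * xval[t]
                L[i, j] = scratch[t]
    return acc, ll_delta


@njit(cache=True)
def gamma_update(gamma, C, D, Y, L, M, alphav, lik_w):
    """Joint Dirichlet(M*gamma) proposal for the popularity vector, with the
    asymmetric-proposal correction; accepts or rejects all components at
    once.  Returns (accepted flag, accepted log-lik delta)."""
    n = gamma.shape[0]
    g = np.empty(n)
    ok = False
    for _attempt in range(50):
        tot = 0.0
        for j in range(n):
            gj = np.random.gamma(M * gamma[j], 1.0)
            g[j] = gj
            tot += gj
        ok = tot > 0.0
        if ok:
            for j in range(n):
                g[j] = g[j] / tot
                if g[j] < 1e-12:
                    ok = False
        if ok:
            break
    if not ok:
        # floor-and-renormalise fallback after repeated underflow
        s = 0.0
        for j in range(n):
            if g[j] < 1e-12:
                g[j] = 1e-12
            s += g[j]
        for j in range(n):
            g[j] /= s
    Lnew = np.empty((n, n))
    delta = 0.0
    for i in range(n):
        Lnew[i, i] = 0.0
        for j in range(n):
            if i == j:
                continue
            v = bern_ll(C[i, j] - D[i, j] / g[j], Y[i, j])
            Lnew[i, j] = v
            delta += v - L[i, j]
    ll_part = delta
    delta *= lik_w
    for j in range(n):
        lg = math.log(g[j])
        lo = math.log(gamma[j])
        delta += (alphav[j] - 1.0) * (lg - lo)
        # q(gamma | M g) - q(g | M gamma); the lgamma(M) totals cancel
        delta += -math.lgamma(M * g[j]) + (M * g[j] - 1.0) * lo
        delta -= -math.lgamma(M * gamma[j]) + (M * gamma[j] - 1.0) * lg
    if math.log(np.random.random()) < delta:
        for j in range(n):
            gamma[j] = g[j]
        L[:, :] = Lnew
        return 1, ll_part
    return 0, 0.0
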