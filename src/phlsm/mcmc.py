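"""MH-within-Gibbs samplers for the penalized homophily latent space model.

One sampler iteration performs, in order: a random-walk MH update of every
latent position, a Gibbs draw of the latent variance, random-walk MH updates
of every regression coefficient, Gibbs draws of the per-coefficient ridge
precisions or lasso rates, a joint Dirichlet MH move of the popularity
vector, and (optionally) one conjugate sweep of the Gaussian-mixture latent
prior for clustered networks.  Latent positions are identified only up to
rigid motions; every stored draw is Procrustes-aligned to the initial MDS
configuration so that chains of coordinates are interpretable.

Initial values follow the model's own ad hoc strategies: classical MDS of
rescaled geodesic distances for Z, the degree-based formula for gamma, the
empirical latent variance for sigma2 (which also sets the IG prior scale
phi), and a fixed-intercept logistic regression for beta.

Step sizes for the two random walks are Robbins-Monro adapted during
burn-in only (targeting roughly 25-40% acceptance) and frozen at the start
of monitoring, so the recorded chain is valid Metropolis-Hastings.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import shortest_path
from scipy.special import gammaln

from . import _kernels
from .model import (BETA0, Hyperparams, LatentState, MixtureState,
                    PopularityState, RegressionState, logpost_beta, logpost_gamma,
                    logpost_z)
from .netdata import DegreeSummary, DirectedNetwork, PairwiseCovariates, degrees

logger = logging.getLogger(__name__)


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``M`` is the concentration of the Dirichlet(M*gamma) proposal for the
    popularity vector; it must exceed n so every proposal concentration
    exceeds 1.
    ``lik_weight`` tempers the likelihood (0 turns it off entirely, which
    makes the sampler target the prior - used by diagnostic tests only).
    """

    burn_in: int = 15000
    monitor: int = 50000
    thin: int = 10
    M: float = 5e6
    z_step: float | None = None       # default 0.05 * sqrt(sigma2_init)
    beta_step: float = 0.1
    adapt: bool = True
    target_accept: float = 0.3
    seed: int | None = None
    penalty: str = "ridge"            # "ridge" | "lasso"
    mixture: bool = False
    G: int = 1
    d: int = 2
    init: str = "informative"         # "informative" | "random"
    lik_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.monitor < 0:
            raise ValueError("burn_in and monitor must be non-negative")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")
        if self.penalty not in ("ridge", "lasso"):
            raise ValueError("penalty must be 'ridge' or 'lasso'")
        if self.mixture and self.G < 1:
            raise ValueError("mixture mode needs G >= 1")


@dataclass
class PosteriorSamples:
    """Stored post-burn-in draws (thinned) plus sampler bookkeeping."""

    Z: np.ndarray               # (S, n, d), Procrustes-aligned
    beta: np.ndarray            # (S, p)
    gamma: np.ndarray           # (S, n)
    sigma2: np.ndarray          # (S,)
    tau2: np.ndarray | None     # (S, p) in ridge mode
    lam: np.ndarray | None      # (S, p) in lasso mode
    loglik: np.ndarray          # per-iteration trace (burn-in + monitor)
    accept_rates: dict
    Z_ref: np.ndarray
    node_ids: list[str]
    config: MCMCConfig
    mix_weights: np.ndarray | None = None   # (S, G)
    mix_means: np.ndarray | None = None     # (S, G, d)
    mix_variances: np.ndarray | None = None  # (S, G)
    mix_labels: np.ndarray | None = None    # (S, n)

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd/quantiles per scalar parameter."""
        rows = []

        def add(name, chain):
            q = np.quantile(chain, [0.025, 0.5, 0.975]) if len(chain) else [np.nan] * 3
            rows.append({"param": name, "mean": np.mean(chain) if len(chain) else np.nan,
                         "sd": np.std(chain, ddof=1) if len(chain) > 1 else np.nan,
                         "q2.5": q[0], "q50": q[1], "q97.5": q[2]})

        for k in range(self.beta.shape[1]):
            add(f"beta[{k + 1}]", self.beta[:, k])
        add("sigma2", self.sigma2)
        for j, nid in enumerate(self.node_ids):
            add(f"gamma[{nid}]", self.gamma[:, j])
        return pd.DataFrame(rows)

    def save(self, path: str) -> None:
        payload = {"Z": self.Z, "beta": self.beta, "gamma": self.gamma,
                   "sigma2": self.sigma2, "loglik": self.loglik,
                   "Z_ref": self.Z_ref,
                   "node_ids": np.array(self.node_ids, dtype=str)}
        for name in ("tau2", "lam", "mix_weights", "mix_means",
                     "mix_variances", "mix_labels"):
            val = getattr(self, name)
            if val is not None:
                payload[name] = val
        np.savez_compressed(path, **payload)


# ---------------------------------------------------------------------------
# Initialization strategies
# ---------------------------------------------------------------------------

def init_latent(net: DirectedNetwork, d: int = 2) -> np.ndarray:
    """Classical MDS of symmetrized geodesic distances, rescaled by 1/n.

    Directed shortest-path distances are symmetrized with
    d(i,j) <- min(d(i,j), d(j,i)); pairs unreachable in both directions get
    the largest finite distance plus one.  The embedding is column-centered.
    """
    if net.n < 3:
        raise ValueError("latent initialization needs at least 3 nodes")
    n = net.n
    G = shortest_path(net.adjacency.astype(float), method="D", unweighted=True)
    G = np.minimum(G, G.T)
    finite = G[np.isfinite(G)]
    cap = (finite.max() if finite.size else 1.0) + 1.0
    G[~np.isfinite(G)] = cap
    np.fill_diagonal(G, 0.0)
    G = G / n
    # classical MDS: double-center the squared distances, top-d eigenvectors
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (G ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:d]
    lam = np.clip(vals[order], 0.0, None)
    Z0 = vecs[:, order] * np.sqrt(lam)[None, :]
    return Z0 - Z0.mean(axis=0, keepdims=True)


def init_gamma(degs: DegreeSummary) -> np.ndarray:
    """gamma_j = (1 + d_j^in) / (n + sum_h d_h^in): strictly positive,
    sums to one, increasing in in-degree."""
    d_in = degs.d_in
    return (1.0 + d_in) / (len(d_in) + d_in.sum())


def init_sigma2(Z0: np.ndarray) -> float:
    """Empirical variance of the initial positions, (1/2n) sum ||z_i||^2."""
    Z0 = np.asarray(Z0, float)
    s = float((Z0 ** 2).sum()) / (2 * Z0.shape[0])
    if s < 1e-8:
        warnings.warn("initial latent positions are degenerate; flooring sigma2 at 1e-8")
        return 1e-8
    return s


def phi_default(Z0: np.ndarray) -> float:
    """IG prior scale targeting the initial sample variance (E sigma2 = phi
    at nu = 2)."""
    return init_sigma2(Z0)


def init_beta(net: DirectedNetwork, X: PairwiseCovariates) -> np.ndarray:
    """Logistic-regression initializer for beta.

    Plain logistic fit of the vectorized off-diagonal y on X with the
    intercept fixed at 1 (an offset) and no latent/popularity terms.  Falls
    back to zeros under perfect separation or non-convergence.
    """
    if X.p == 0:
        return np.zeros(0)
    import statsmodels.api as sm
    mask = ~np.eye(net.n, dtype=bool)
    y = net.adjacency[mask].astype(float)
    design = X.matrix()[mask.ravel()]
    offset = np.full(len(y), BETA0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, design, family=sm.families.Binomial(),
                         offset=offset).fit(maxiter=100)
        beta = np.asarray(fit.params, float)
        if not np.isfinite(beta).all() or np.abs(beta).max() > 1e3:
            raise ValueError("diverged")
    except Exception:
        warnings.warn("logistic initializer failed (separation?); starting beta at 0")
        beta = np.zeros(X.p)
    return beta


# ---------------------------------------------------------------------------
# Gibbs conditionals
# ---------------------------------------------------------------------------

def gibbs_sigma2(Z: np.ndarray, hyper: Hyperparams,
                 rng: np.random.Generator) -> float:
    """One exact draw from sigma2 | Z ~ IG(nu + n, phi + 0.5 sum ||z_i||^2)."""
    if hyper.phi is None:
        raise ValueError("phi is unset; pass Hyperparams(phi=...) or let "
                         "run_sampler derive it from the initial positions")
    Z = np.asarray(Z, float)
    shape = hyper.nu + Z.shape[0]
    rate = hyper.phi + 0.5 * float((Z ** 2).sum())
    return rate / rng.gamma(shape)


def gibbs_tau2(beta_k: float, k: int, hyper: Hyperparams,
               rng: np.random.Generator) -> float:
    """tau_k^2 | beta_k ~ Gamma(xi_tau + 1/2, rate delta_tau + beta_k^2/2)."""
    shape = hyper.xi_tau[k] + 0.5
    rate = hyper.delta_tau + 0.5 * beta_k ** 2
    return rng.gamma(shape, 1.0 / rate)


def gibbs_lambda(beta_k: float, k: int, hyper: Hyperparams,
                 rng: np.random.Generator) -> float:
    """lambda_k | beta_k ~ Gamma(xi_lam + 1, rate delta_lam + |beta_k|)."""
    shape = hyper.xi_lam[k] + 1.0
    rate = hyper.delta_lam + abs(beta_k)
    return rng.gamma(shape, 1.0 / rate)


# ---------------------------------------------------------------------------
# Single-site MH updates (reference implementations)
# ---------------------------------------------------------------------------

def mh_update_z(i: int, net: DirectedNetwork, X: PairwiseCovariates,
                lat: LatentState, reg: RegressionState, pop: PopularityState,
                step: float, rng: np.random.Generator,
                mix: MixtureState | None = None) -> bool:
    """Gaussian random-walk MH update of z_i (in place).  The proposal is
    symmetric, so the acceptance ratio is just the kernel ratio."""
    cur = lat.Z[i].copy()
    cand = cur + step * rng.standard_normal(lat.Z.shape[1])
    lp_new = logpost_z(i, cand, net, X, lat, reg, pop, mix)
    lp_old = logpost_z(i, cur, net, X, lat, reg, pop, mix)
    if np.log(rng.random()) < lp_new - lp_old:
        lat.Z[i] = cand
        return True
    return False


def mh_update_beta(k: int, net: DirectedNetwork, X: PairwiseCovariates,
                   lat: LatentState, reg: RegressionState, pop: PopularityState,
                   hyper: Hyperparams, step: float,
                   rng: np.random.Generator) -> bool:
    """Random-walk MH update of beta_k: Normal walk in ridge mode, Laplace
    walk in lasso mode (both symmetric)."""
    cur = reg.beta[k]
    if reg.penalty == "ridge":
        cand = cur + step * rng.standard_normal()
    else:
        cand = cur + rng.laplace(scale=step)
    lp_new = logpost_beta(k, cand, net, X, lat, reg, pop, hyper)
    lp_old = logpost_beta(k, cur, net, X, lat, reg, pop, hyper)
    if np.log(rng.random()) < lp_new - lp_old:
        reg.beta[k] = cand
        return True
    return False


def _dirichlet_logpdf(x: np.ndarray, conc: np.ndarray) -> float:
    return float(((conc - 1) * np.log(x)).sum()
                 + gammaln(conc.sum()) - gammaln(conc).sum())


def mh_update_gamma(net: DirectedNetwork, X: PairwiseCovariates,
                    lat: LatentState, reg: RegressionState, pop: PopularityState,
                    hyper: Hyperparams, M: float,
                    rng: np.random.Generator) -> bool:
    """Joint MH move of gamma with a Dirichlet(M*gamma) proposal.

    The proposal is asymmetric, so the acceptance ratio carries the
    correction Dir(gamma | M gamma*) / Dir(gamma* | M gamma); the whole
    vector is kept or replaced at once.
    """
    cur = pop.gamma
    cand = rng.dirichlet(M * cur)
    for _ in range(50):
        if cand.min() >= 1e-12:
            break
        cand = rng.dirichlet(M * cur)
    else:
        cand = np.clip(cand, 1e-12, None)
        cand = cand / cand.sum()
    lp_new = logpost_gamma(cand, net, X, lat, reg, hyper)
    lp_old = logpost_gamma(cur, net, X, lat, reg, hyper)
    corr = _dirichlet_logpdf(cur, M * cand) - _dirichlet_logpdf(cand, M * cur)
    if np.log(rng.random()) < lp_new - lp_old + corr:
        pop.gamma = cand
        return True
    return False


# ---------------------------------------------------------------------------
# Procrustes alignment
# ---------------------------------------------------------------------------

def procrustes_align(Z: np.ndarray, Z_ref: np.ndarray) -> np.ndarray:
    """Optimal rigid motion (translation + rotation/reflection, no scaling)
    of Z onto Z_ref; pairwise distances are preserved."""
    Z = np.asarray(Z, float)
    Z_ref = np.asarray(Z_ref, float)
    if Z.shape != Z_ref.shape:
        raise ValueError("Z and Z_ref must have the same shape")
    mu = Z.mean(axis=0, keepdims=True)
    mu_ref = Z_ref.mean(axis=0, keepdims=True)
    R, _ = orthogonal_procrustes(Z - mu, Z_ref - mu_ref)
    return (Z - mu) @ R + mu_ref


# ---------------------------------------------------------------------------
# Mixture-prior sweep and label-switching post-processing
# ---------------------------------------------------------------------------

@dataclass
class MixturePriors:
    """Conjugate hyperpriors of the clustered latent prior."""

    dir_conc: float = 1.0       # Dirichlet prior on the weights
    mean_var: float = 1.0       # prior variance of the component means
    var_shape: float = 2.0      # IG shape for component variances
    var_scale: float = 1.0      # IG scale for component variances


def mixture_gibbs(Z: np.ndarray, mix: MixtureState, priors: MixturePriors,
                  rng: np.random.Generator) -> MixtureState:
    """One conjugate sweep: labels, weights, means, variances.

    Empty clusters fall back to prior draws.
    """
    from .model import cluster_membership_probs
    Z = np.asarray(Z, float)
    n, d = Z.shape
    G = mix.G
    probs = np.stack([cluster_membership_probs(Z[i], mix) for i in range(n)])
    u = rng.random(n)
    labels = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(0, G - 1)
    counts = np.bincount(labels, minlength=G)
    weights = rng.dirichlet(priors.dir_conc + counts)
    means = np.empty((G, d))
    variances = np.empty(G)
    for g in range(G):
        members = Z[labels == g]
        m = len(members)
        if m == 0:
            means[g] = rng.normal(0.0, np.sqrt(priors.mean_var), size=d)
            variances[g] = priors.var_scale / rng.gamma(priors.var_shape)
            continue
        post_var = 1.0 / (m / mix.variances[g] + 1.0 / priors.mean_var)
        post_mean = post_var * members.sum(axis=0) / mix.variances[g]
        means[g] = post_mean + np.sqrt(post_var) * rng.standard_normal(d)
        sq = ((members - means[g]) ** 2).sum()
        variances[g] = (priors.var_scale + 0.5 * sq) \
            / rng.gamma(priors.var_shape + 0.5 * m * d)
    return MixtureState(weights, means, variances, labels)


def _membership_matrix(Z: np.ndarray, mix: MixtureState) -> np.ndarray:
    from .model import cluster_membership_probs
    return np.stack([cluster_membership_probs(z, mix) for z in Z])


def relabel_clusters(samples: PosteriorSamples) -> tuple[PosteriorSamples, dict]:
    """Undo label switching across stored mixture draws.

    For each draw the permutation of {1..G} minimizing the KL divergence
    between permuted membership probabilities and the running average of
    already-relabeled memberships is applied (exhaustive over G!
    permutations; G <= 8 enforced).
    """
    if samples.mix_weights is None:
        raise ValueError("samples carry no mixture draws")
    G = samples.mix_weights.shape[1]
    if G > 8:
        raise ValueError("exhaustive relabeling supports G <= 8; use a "
                         "different relabeling scheme for larger G")
    S = samples.n_samples
    perms = list(itertools.permutations(range(G)))
    out = replace(samples,
                  mix_weights=samples.mix_weights.copy(),
                  mix_means=samples.mix_means.copy(),
                  mix_variances=samples.mix_variances.copy(),
                  mix_labels=samples.mix_labels.copy())
    ref = None
    eps = 1e-300
    kl_before = np.zeros(S)
    kl_after = np.zeros(S)
    for s in range(S):
        mix = MixtureState(out.mix_weights[s], out.mix_means[s],
                           out.mix_variances[s], out.mix_labels[s])
        R = _membership_matrix(out.Z[s], mix)
        if ref is None:
            ref = R.copy()
            continue

        def kl(mat):
            return float((mat * (np.log(mat + eps) - np.log(ref + eps))).sum())

        kls = [kl(R[:, list(pm)]) for pm in perms]
        best = perms[int(np.argmin(kls))]
        kl_before[s] = kls[0]
        kl_after[s] = min(kls)
        idx = list(best)
        out.mix_weights[s] = out.mix_weights[s, idx]
        out.mix_means[s] = out.mix_means[s, idx]
        out.mix_variances[s] = out.mix_variances[s, idx]
        inv = np.argsort(idx)
        out.mix_labels[s] = inv[out.mix_labels[s]]
        R = R[:, idx]
        ref = (ref * s + R) / (s + 1)
    return out, {"kl_before": kl_before, "kl_after": kl_after}


# ---------------------------------------------------------------------------
# The full sampler
# ---------------------------------------------------------------------------

def _nonzero_layout(X: PairwiseCovariates):
    """Flattened nonzero-entry layout of the covariate tensor for the
    compiled beta sweep (diagonal excluded)."""
    p, n, _ = X.tensor.shape
    offs = np.zeros(p + 1, dtype=np.int64)
    ii, jj, vv = [], [], []
    diag = np.eye(n, dtype=bool)
    for k in range(p):
        mask = (X.tensor[k] != 0) & ~diag
        i, j = np.nonzero(mask)
        offs[k + 1] = offs[k] + len(i)
        ii.append(i)
        jj.append(j)
        vv.append(X.tensor[k][mask])
    if p == 0:
        return offs, np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0)
    return (offs, np.concatenate(ii).astype(np.int64),
            np.concatenate(jj).astype(np.int64), np.concatenate(vv))


def run_sampler(net: DirectedNetwork, X: PairwiseCovariates | None,
                cfg: MCMCConfig, hyper: Hyperparams | None = None) -> PosteriorSamples:
    """Run the full MH-within-Gibbs sampler and return stored draws.

    Reproducibility contract: the same (inputs, config, seed) produce
    bit-identical samples.
    """
    if X is None:
        X = PairwiseCovariates.empty(net.n)
    n, p, d = net.n, X.p, cfg.d
    Y = net.adjacency.astype(np.float64)

    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    _kernels.seed_kernels(np.uint32(ss.generate_state(1, np.uint32)[0]))

    # --- initial values -----------------------------------------------------
    Z_ref = init_latent(net, d)
    if cfg.init == "informative":
        Z = Z_ref.copy()
        gamma = init_gamma(degrees(net))
        beta = init_beta(net, X)
    elif cfg.init == "random":
        Z = rng.standard_normal((n, d))
        gamma = rng.dirichlet(np.ones(n))
        beta = np.zeros(p)
    else:
        raise ValueError("init must be 'informative' or 'random'")
    sigma2 = init_sigma2(Z_ref)
    if hyper is None:
        hyper = Hyperparams.for_covariates(X, phi=phi_default(Z_ref))
    elif hyper.phi is None:
        hyper = replace(hyper, phi=phi_default(Z_ref))
    if len(hyper.xi_tau) not in (p, 1) and p:
        raise ValueError("hyperparameter shapes must match the covariate count")
    xi_tau = np.resize(hyper.xi_tau, max(p, 1))
    xi_lam = np.resize(hyper.xi_lam, max(p, 1))

    lasso = cfg.penalty == "lasso"
    if lasso:
        lam = rng.gamma(xi_lam[:p] + 1.0, 1.0 / (hyper.delta_lam + np.abs(beta)))
        tau2 = None
    else:
        tau2 = rng.gamma(xi_tau[:p] + 0.5, 1.0 / (hyper.delta_tau + 0.5 * beta ** 2))
        lam = None

    mix = None
    mix_priors = None
    if cfg.mixture:
        labels = rng.integers(0, cfg.G, size=n)
        mix = MixtureState(np.full(cfg.G, 1.0 / cfg.G),
                           np.zeros((cfg.G, d)),
                           np.full(cfg.G, max(sigma2, 1e-8)),
                           labels)
        mix_priors = MixturePriors(mean_var=10.0 * max(sigma2, 1e-8),
                                   var_scale=max(sigma2, 1e-8))

    alphav = hyper.alpha_vector(n)
    z_step = cfg.z_step if cfg.z_step is not None else 0.05 * np.sqrt(sigma2)
    beta_step = np.full(max(p, 1), cfg.beta_step)
    acc_k = np.zeros(max(p, 1), dtype=np.int64)
    acc_k_win = np.zeros(max(p, 1), dtype=np.int64)
    if cfg.M <= n:
        raise ValueError("Dirichlet proposal concentration M must exceed n")

    # --- state caches -------------------------------------------------------
    D = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=-1)
    C = BETA0 + (np.tensordot(beta, X.tensor, axes=(0, 0)) if p else np.zeros((n, n)))
    C = np.ascontiguousarray(C, dtype=np.float64)
    D = np.ascontiguousarray(D, dtype=np.float64)
    Z = np.ascontiguousarray(Z, dtype=np.float64)
    gamma = np.ascontiguousarray(gamma, dtype=np.float64)
    beta = np.ascontiguousarray(beta, dtype=np.float64)
    offs, idx_i, idx_j, xval = _nonzero_layout(X)
    scratch = np.empty(max(int(offs[-1]), 1))
    penalty_code = _kernels.LASSO if lasso else _kernels.RIDGE
    _empty = np.zeros((1, d))
    _empty_w = np.ones(1)

    L = np.empty((n, n))
    ll = _kernels.fill_ll(C, D, gamma, Y, L)
    if not np.isfinite(ll):
        raise RuntimeError("non-finite log-likelihood at initialization; "
                           "check inputs and initial values")

    total = cfg.burn_in + cfg.monitor
    n_store = sum(1 for t in range(cfg.burn_in, total) if (t - cfg.burn_in) % cfg.thin == 0)
    store = {
        "Z": np.empty((n_store, n, d)), "beta": np.empty((n_store, p)),
        "gamma": np.empty((n_store, n)), "sigma2": np.empty(n_store),
        "pen": np.empty((n_store, p)),
    }
    if cfg.mixture:
        store["mw"] = np.empty((n_store, cfg.G))
        store["mm"] = np.empty((n_store, cfg.G, d))
        store["mv"] = np.empty((n_store, cfg.G))
        store["ml"] = np.empty((n_store, n), dtype=int)
    trace = np.empty(total)
    acc = {"z": 0, "beta": 0, "gamma": 0}
    acc_win = {"z": 0, "beta": 0}
    s_idx = 0
    ADAPT_EVERY = 50

    for t in range(total):
        mix_on = mix is not None
        a_z, dll = _kernels.z_sweep(
            Z, D, C, gamma, Y, L, z_step, sigma2, mix_on,
            mix.weights if mix_on else _empty_w,
            mix.means if mix_on else _empty,
            mix.variances if mix_on else _empty_w,
            cfg.lik_weight)
        ll += dll
        acc["z"] += a_z
        acc_win["z"] += a_z
        # NOTE: alignment happens on the stored snapshots, not on the chain
        # state: the likelihood is rigid-motion invariant but the Gaussian
        # prior is not translation invariant, so re-centering the state each
        # iteration would bias sigma2 (and hence all distances) downward.

        if mix_on:
            mix = mixture_gibbs(Z, mix, mix_priors, rng)
            sigma2 = float(mix.variances @ mix.weights)  # summary scale only
        else:
            sigma2 = gibbs_sigma2(Z, hyper, rng)

        if p:
            pen_par = lam if lasso else tau2
            a_b, dll = _kernels.beta_sweep(beta, C, D, gamma, Y, L, offs, idx_i,
                                           idx_j, xval, scratch, beta_step,
                                           acc_k_win, penalty_code, pen_par,
                                           cfg.lik_weight)
            ll += dll
            acc["beta"] += a_b
            acc_win["beta"] += a_b
            if lasso:
                lam = rng.gamma(xi_lam[:p] + 1.0,
                                1.0 / (hyper.delta_lam + np.abs(beta)))
            else:
                tau2 = rng.gamma(xi_tau[:p] + 0.5,
                                 1.0 / (hyper.delta_tau + 0.5 * beta ** 2))

        a_g, dll = _kernels.gamma_update(gamma, C, D, Y, L, cfg.M, alphav,
                                         cfg.lik_weight)
        ll += dll
        acc["gamma"] += a_g
        trace[t] = ll

        if cfg.adapt and t < cfg.burn_in and (t + 1) % ADAPT_EVERY == 0:
            rate_z = acc_win["z"] / (ADAPT_EVERY * n)
            z_step *= np.exp(0.5 * (rate_z - cfg.target_accept))
            if p:
                rate_k = acc_k_win[:p] / ADAPT_EVERY
                beta_step[:p] *= np.exp(0.5 * (rate_k - cfg.target_accept))
            acc_win = {"z": 0, "beta": 0}
            acc_k += acc_k_win
            acc_k_win[:] = 0
        if (t + 1) % 1000 == 0:
            ll = _kernels.fill_ll(C, D, gamma, Y, L)  # refresh fp drift

        if t >= cfg.burn_in and (t - cfg.burn_in) % cfg.thin == 0:
            mu = Z.mean(axis=0, keepdims=True)
            R, _ = orthogonal_procrustes(Z - mu, Z_ref)
            store["Z"][s_idx] = (Z - mu) @ R
            store["beta"][s_idx] = beta
            store["gamma"][s_idx] = gamma
            store["sigma2"][s_idx] = sigma2
            store["pen"][s_idx] = lam if lasso else tau2
            if cfg.mixture:
                store["mw"][s_idx] = mix.weights
                store["mm"][s_idx] = (mix.means - mu) @ R  # same frame as Z
                store["mv"][s_idx] = mix.variances
                store["ml"][s_idx] = mix.labels
            s_idx += 1

    rates = {"z": acc["z"] / (total * n) if total else np.nan,
             "beta": acc["beta"] / (total * p) if total and p else np.nan,
             "gamma": acc["gamma"] / total if total else np.nan,
             "z_step": float(z_step),
             "beta_step": float(np.mean(beta_step[:p])) if p else float(cfg.beta_step)}
    logger.info("sampler finished: acceptance %s", rates)
    return PosteriorSamples(
        Z=store["Z"], beta=store["beta"], gamma=store["gamma"],
        sigma2=store["sigma2"],
        tau2=None if lasso else store["pen"],
        lam=store["pen"] if lasso else None,
        loglik=trace, accept_rates=rates, Z_ref=Z_ref,
        node_ids=list(net.node_ids), config=cfg,
        mix_weights=store.get("mw"), mix_means=store.get("mm"),
        mix_variances=store.get("mv"), mix_labels=store.get("ml"))
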