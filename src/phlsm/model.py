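"""Probability model for the penalized homophily latent space model.

The log-odds that node i follows node j is

    eta_ij = beta0 + beta' x_ij - ||z_i - z_j|| / gamma_j,

with z_i in R^d latent positions (Gaussian prior, variance sigma2),
gamma a popularity vector on the simplex (larger gamma_j makes node j
easier to follow), and beta regression coefficients on symmetric pairwise
covariates, penalized either by a Normal (ridge) or Laplace (adaptive
LASSO) prior with per-coefficient Gamma-distributed precision/rate.
The intercept beta0 is fixed at 1 for identification, and Sum_j gamma_j = 1.

All kernel evaluations work in log space: edge probabilities are never
materialised during posterior computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .netdata import DirectedNetwork, PairwiseCovariates

BETA0 = 1.0  # identification constraint: intercept fixed at 1


@dataclass
class LatentState:
    Z: np.ndarray          # (n, d)
    sigma2: float

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, float))
        if self.Z.ndim != 2 or self.Z.shape[1] < 1:
            raise ValueError("Z must be an (n, d) matrix with d >= 1")
        if not np.isfinite(self.Z).all():
            raise ValueError("latent coordinates must be finite")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class RegressionState:
    """Coefficients plus their penalty state (exactly one of tau2/lam)."""

    beta: np.ndarray
    penalty: str = "ridge"              # "ridge" | "lasso"
    tau2: np.ndarray | None = None      # ridge precisions tau_k^2
    lam: np.ndarray | None = None       # lasso rates lambda_k
    beta0: float = BETA0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float).ravel()
        if self.penalty not in ("ridge", "lasso"):
            raise ValueError("penalty must be 'ridge' or 'lasso'")
        if (self.tau2 is None) == (self.lam is None) and len(self.beta):
            raise ValueError("exactly one of tau2 (ridge) or lam (lasso) must be set")
        if self.tau2 is not None:
            self.tau2 = np.asarray(self.tau2, float).ravel()
            if (self.tau2 <= 0).any() or len(self.tau2) != len(self.beta):
                raise ValueError("tau2 must be positive, one per coefficient")
        if self.lam is not None:
            self.lam = np.asarray(self.lam, float).ravel()
            if (self.lam <= 0).any() or len(self.lam) != len(self.beta):
                raise ValueError("lam must be positive, one per coefficient")


@dataclass
class PopularityState:
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, float).ravel()
        if ((self.gamma <= 0) | (self.gamma >= 1)).any():
            raise ValueError("every gamma_j must lie in (0, 1)")
        if abs(self.gamma.sum() - 1.0) > 1e-8:
            raise ValueError("gamma must sum to 1")


@dataclass
class Hyperparams:
    """Prior hyperparameters.

    sigma2 ~ IG(nu, phi); tau_k^2 ~ Gamma(xi_tau_k, rate delta_tau);
    lambda_k ~ Gamma(xi_lam_k, rate delta_lam); gamma ~ Dirichlet(alpha).
    The Gamma shapes default by attribute type: categorical covariates get
    xi_tau = 4 / xi_lam = 8, continuous ones xi_tau = 2 / xi_lam = 4.
    """

    nu: float = 2.0
    phi: float | None = None    # None: set from the initial latent variance
    xi_tau: np.ndarray = field(default_factory=lambda: np.array([2.0]))
    delta_tau: float = 0.05
    xi_lam: np.ndarray = field(default_factory=lambda: np.array([4.0]))
    delta_lam: float = 0.1
    alpha: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        self.xi_tau = np.atleast_1d(np.asarray(self.xi_tau, float))
        self.xi_lam = np.atleast_1d(np.asarray(self.xi_lam, float))
        for name in ("nu", "delta_tau", "delta_lam"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.phi is not None and not self.phi > 0:
            raise ValueError("phi must be positive")
        if (self.xi_tau <= 0).any() or (self.xi_lam <= 0).any():
            raise ValueError("Gamma shapes must be positive")
        if np.any(np.asarray(self.alpha, float) <= 0):
            raise ValueError("Dirichlet alpha must be strictly positive")

    @classmethod
    def for_covariates(cls, X: PairwiseCovariates, **kw) -> "Hyperparams":
        """Type-aware Gamma shapes, one per covariate column."""
        xi_tau = np.array([4.0 if t == "categorical" else 2.0 for t in X.types])
        xi_lam = np.array([8.0 if t == "categorical" else 4.0 for t in X.types])
        if X.p == 0:
            xi_tau = np.array([2.0])
            xi_lam = np.array([4.0])
        return cls(xi_tau=xi_tau, xi_lam=xi_lam, **kw)

    def alpha_vector(self, n: int) -> np.ndarray:
        a = np.asarray(self.alpha, float)
        return np.full(n, float(a)) if a.ndim == 0 else a


@dataclass
class MixtureState:
    """Gaussian-mixture latent prior for clustered networks."""

    weights: np.ndarray    # (G,) simplex
    means: np.ndarray      # (G, d)
    variances: np.ndarray  # (G,)
    labels: np.ndarray     # (n,) in {0..G-1}

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float).ravel()
        self.means = np.atleast_2d(np.asarray(self.means, float))
        self.variances = np.asarray(self.variances, float).ravel()
        self.labels = np.asarray(self.labels, int).ravel()
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("mixture variances must be positive")

    @property
    def G(self) -> int:
        return len(self.weights)


# ---------------------------------------------------------------------------
# Linear predictor and likelihood
# ---------------------------------------------------------------------------

def _xbeta(X: PairwiseCovariates | np.ndarray, beta: np.ndarray) -> np.ndarray:
    tensor = X.tensor if isinstance(X, PairwiseCovariates) else np.asarray(X)
    if tensor.shape[0] == 0:
        return 0.0
    return np.tensordot(beta, tensor, axes=(0, 0))


def linear_predictor(Z: np.ndarray, X: PairwiseCovariates, reg: RegressionState,
                     pop: PopularityState, i: int, j: int) -> float:
    """Log-odds eta_ij for a single ordered pair (i != j)."""
    if i == j:
        raise ValueError("eta is undefined on the diagonal")
    if pop.gamma[j] <= 0:
        raise ValueError("gamma_j must be positive")
    dist = float(np.linalg.norm(np.asarray(Z, float)[i] - np.asarray(Z, float)[j]))
    xb = 0.0 if X.p == 0 else float(reg.beta @ X.tensor[:, i, j])
    return reg.beta0 + xb - dist / pop.gamma[j]


def linear_predictor_matrix(Z: np.ndarray, X: PairwiseCovariates,
                            reg: RegressionState, pop: PopularityState) -> np.ndarray:
    """All n(n-1) log-odds as an (n, n) matrix with NaN on the diagonal."""
    Z = np.asarray(Z, float)
    D = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=-1)
    eta = reg.beta0 + _xbeta(X, reg.beta) - D / pop.gamma[None, :]
    eta = np.asarray(eta, float)
    np.fill_diagonal(eta, np.nan)
    return eta


def _bernoulli_ll(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """y*eta - log(1 + exp(eta)), overflow-safe."""
    # softplus(eta) = max(eta, 0) + log1p(exp(-|eta|))
    sp = np.maximum(eta, 0.0) + np.log1p(np.exp(-np.abs(eta)))
    return y * eta - sp


def log_likelihood(net: DirectedNetwork, eta: np.ndarray) -> float:
    """Bernoulli log-likelihood summed over ordered pairs i != j."""
    mask = ~np.eye(net.n, dtype=bool)
    e = np.asarray(eta, float)[mask]
    if not np.isfinite(e).all():
        raise ValueError("eta must be finite off the diagonal")
    return float(_bernoulli_ll(e, net.adjacency[mask]).sum())


# ---------------------------------------------------------------------------
# Full-conditional (unnormalized) log posterior kernels
# ---------------------------------------------------------------------------

def _pair_ll_for_node(i: int, Zi: np.ndarray, Z: np.ndarray, X: PairwiseCovariates,
                      reg: RegressionState, pop: PopularityState,
                      Y: np.ndarray) -> float:
    """Sum of the 2(n-1) pair log-probabilities involving node i, with z_i
    replaced by ``Zi``."""
    n = Z.shape[0]
    others = np.arange(n) != i
    d = np.linalg.norm(Z[others] - Zi[None, :], axis=1)
    if X.p:
        xb_out = reg.beta @ X.tensor[:, i, others]
        xb_in = reg.beta @ X.tensor[:, others, i]
    else:
        xb_out = xb_in = 0.0
    eta_out = reg.beta0 + xb_out - d / pop.gamma[others]
    eta_in = reg.beta0 + xb_in - d / pop.gamma[i]
    return float(_bernoulli_ll(eta_out, Y[i, others]).sum()
                 + _bernoulli_ll(eta_in, Y[others, i]).sum())


def _latent_log_prior(zi: np.ndarray, lat: LatentState,
                      mix: MixtureState | None) -> float:
    d = len(zi)
    if mix is None:
        return float(-0.5 * d * np.log(2 * np.pi * lat.sigma2)
                     - 0.5 * (zi @ zi) / lat.sigma2)
    comp = (np.log(mix.weights)
            - 0.5 * d * np.log(2 * np.pi * mix.variances)
            - 0.5 * ((zi[None, :] - mix.means) ** 2).sum(axis=1) / mix.variances)
    return float(logsumexp(comp))


def logpost_z(i: int, zi: np.ndarray, net: DirectedNetwork, X: PairwiseCovariates,
              lat: LatentState, reg: RegressionState, pop: PopularityState,
              mix: MixtureState | None = None) -> float:
    """Unnormalized log full-conditional of z_i at candidate ``zi``.

    With a mixture latent prior the single-Gaussian prior factor is replaced
    by the mixture density.
    """
    zi = np.asarray(zi, float).ravel()
    ll = _pair_ll_for_node(i, zi, lat.Z, X, reg, pop, net.adjacency)
    return ll + _latent_log_prior(zi, lat, mix)


def logpost_beta(k: int, beta_k: float, net: DirectedNetwork, X: PairwiseCovariates,
                 lat: LatentState, reg: RegressionState, pop: PopularityState,
                 hyper: Hyperparams) -> float:
    """Unnormalized log full-conditional of beta_k: full Bernoulli likelihood
    plus the Normal (ridge) or Laplace (lasso) log prior."""
    if not 0 <= k < X.p:
        raise IndexError("coefficient index out of range")
    beta = reg.beta.copy()
    beta[k] = beta_k
    trial = RegressionState(beta, penalty=reg.penalty,
                            tau2=reg.tau2, lam=reg.lam, beta0=reg.beta0)
    eta = linear_predictor_matrix(lat.Z, X, trial, pop)
    np.fill_diagonal(eta, 0.0)
    ll = log_likelihood(net, eta)
    if reg.penalty == "ridge":
        t2 = reg.tau2[k]
        prior = 0.5 * np.log(t2 / (2 * np.pi)) - 0.5 * t2 * beta_k ** 2
    else:
        lam = reg.lam[k]
        prior = np.log(lam / 2.0) - lam * abs(beta_k)
    return ll + float(prior)


def logpost_gamma(gamma: np.ndarray, net: DirectedNetwork, X: PairwiseCovariates,
                  lat: LatentState, reg: RegressionState,
                  hyper: Hyperparams) -> float:
    """Unnormalized log full-conditional of the popularity vector gamma."""
    gamma = np.asarray(gamma, float).ravel()
    if ((gamma <= 0) | (gamma >= 1)).any():
        raise ValueError("gamma components must lie in (0, 1)")
    pop = PopularityState(gamma / gamma.sum())
    eta = linear_predictor_matrix(lat.Z, X, reg, pop)
    np.fill_diagonal(eta, 0.0)
    ll = log_likelihood(net, eta)
    a = hyper.alpha_vector(len(gamma))
    prior = float(((a - 1) * np.log(gamma)).sum()
                  + gammaln(a.sum()) - gammaln(a).sum())
    return ll + prior


def cluster_membership_probs(zi: np.ndarray, mix: MixtureState) -> np.ndarray:
    """P(k_i = g | z_i, mixture), computed in log space (never NaN)."""
    zi = np.asarray(zi, float).ravel()
    d = len(zi)
    logp = (np.log(mix.weights)
            - 0.5 * d * np.log(2 * np.pi * mix.variances)
            - 0.5 * ((zi[None, :] - mix.means) ** 2).sum(axis=1) / mix.variances)
    logp -= logsumexp(logp)
    probs = np.exp(logp)
    return probs / probs.sum()
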