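"""Generative simulator for semi-scale-free directed networks.

Networks are drawn from the model itself: popularity concentrations
alpha_i follow a truncated discrete power law P(l) proportional to l^-theta
(l = 1..l_max), gamma ~ Dirichlet(alpha) puts power-law heterogeneity into
the in-degrees, latent positions are i.i.d. bivariate Gaussians, and each
ordered pair links independently with probability logistic(eta_ij).
Ground truth (Z, gamma, alpha, beta, sigma2) is retained for recovery
studies.

Smaller theta produces heavier-tailed alpha, hence stronger hub dominance;
out-degree heterogeneity stays mild, mimicking follow-limit behaviour of
real microblog platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netdata import AttributeTable, DirectedNetwork, PairwiseCovariates, pairwise_covariates


@dataclass
class SimulationSpec:
    """Generative parameters with ground truth retained.

    ``attr_types`` gives one of "continuous" (standard Normal) or "binary"
    (Bernoulli(0.5)) per attribute; ``beta`` must match its length.
    """

    n: int
    theta: float
    sigma2: float = 3e-4
    beta: tuple[float, ...] = ()
    attr_types: tuple[str, ...] = ()
    beta0: float = 1.0
    d: int = 2
    l_max: int | None = None       # power-law support cap, default n
    epsilon: float = 1e-3          # continuous-attribute normalisation floor
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("simulation needs n >= 10")
        if not self.theta > 1:
            raise ValueError("power-law exponent theta must exceed 1")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        if len(self.beta) != len(self.attr_types):
            raise ValueError("beta and attr_types must have equal length")
        bad = set(self.attr_types) - {"continuous", "binary"}
        if bad:
            raise ValueError(f"unknown attribute scheme(s): {sorted(bad)}")
        if self.l_max is None:
            self.l_max = self.n
        if self.l_max < 1:
            raise ValueError("l_max must be at least 1")


@dataclass
class SimulatedNetwork:
    net: DirectedNetwork
    attrs: AttributeTable | None
    X: PairwiseCovariates
    truth: dict = field(default_factory=dict)


def sample_powerlaw_alpha(n: int, theta: float, l_max: int,
                          rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. draws from the truncated discrete power law P(l) ∝ l^-theta,
    l in {1..l_max} (normalised by the truncated zeta sum)."""
    if not theta > 1:
        raise ValueError("theta must exceed 1")
    support = np.arange(1, l_max + 1)
    w = support.astype(float) ** (-theta)
    return rng.choice(support, size=n, p=w / w.sum())


def simulate_network(spec: SimulationSpec) -> SimulatedNetwork:
    """Draw one network (plus attributes and ground truth) from the model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    alpha = sample_powerlaw_alpha(n, spec.theta, spec.l_max, rng)
    gamma = rng.dirichlet(alpha.astype(float))
    Z = rng.normal(0.0, np.sqrt(spec.sigma2), size=(n, spec.d))

    attrs = None
    X = PairwiseCovariates.empty(n)
    if spec.attr_types:
        cols = {}
        types = {}
        for k, typ in enumerate(spec.attr_types):
            name = f"a{k + 1}"
            if typ == "continuous":
                cols[name] = rng.normal(size=n)
                types[name] = "continuous"
            else:
                cols[name] = rng.integers(0, 2, size=n).astype(int)
                types[name] = "categorical"
        frame = pd.DataFrame(cols, index=[f"v{i + 1}" for i in range(n)])
        attrs = AttributeTable(frame, types)
        X = pairwise_covariates(attrs, epsilon=spec.epsilon)

    D = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=-1)
    eta = spec.beta0 - D / gamma[None, :]
    if X.p:
        eta = eta + np.tensordot(np.asarray(spec.beta, float), X.tensor, axes=(0, 0))
    with np.errstate(over="ignore"):
        P = 1.0 / (1.0 + np.exp(-eta))
    Y = (rng.random((n, n)) < P).astype(np.int8)
    np.fill_diagonal(Y, 0)
    ids = [f"v{i + 1}" for i in range(n)]
    net = DirectedNetwork(ids, Y)
    truth = {"Z": Z, "gamma": gamma, "alpha": alpha,
             "beta": np.asarray(spec.beta, float), "sigma2": spec.sigma2,
             "beta0": spec.beta0, "theta": spec.theta}
    return SimulatedNetwork(net, attrs, X, truth)


def make_sparse_beta(p: int, active_indices: tuple[int, ...],
                     values: tuple[float, ...]) -> np.ndarray:
    """True coefficient vector with the given sparsity pattern.

    ``active_indices`` are 0-based; ``values`` match them positionally.
    """
    if len(active_indices) != len(values):
        raise ValueError("active_indices and values must match in length")
    beta = np.zeros(p)
    for idx, val in zip(active_indices, values):
        if not 0 <= idx < p:
            raise IndexError(f"active index {idx} out of range for p={p}")
        beta[idx] = val
    return beta


# ---------------------------------------------------------------------------
# Presets reproducing the three benchmark simulation designs
# ---------------------------------------------------------------------------

def preset_table1(theta: float = 2.0, n: int = 500, seed: int | None = None) -> SimulationSpec:
    """No-covariate design: n = 500, sigma2 = 3e-4, power-law popularity."""
    return SimulationSpec(n=n, theta=theta, sigma2=3e-4, seed=seed)


def preset_example2(n: int = 500, seed: int | None = None) -> SimulationSpec:
    """Two-covariate design: one continuous N(0,1), one Bernoulli(0.5)
    attribute with beta = (0.5, -1), theta = 2."""
    return SimulationSpec(n=n, theta=2.0, sigma2=3e-4, beta=(0.5, -1.0),
                          attr_types=("continuous", "binary"), seed=seed)


# magnitudes of the active coefficients in the sparse designs; the design
# fixes which coefficients are active, values alternate +-1
_LASSO_VALUE = 1.0


def lasso40_beta() -> tuple[np.ndarray, tuple[str, ...]]:
    """n=50, p=40 sparse design: attributes 1-20 binary, 21-40 continuous;
    actives at 1-based positions 5, 15, 25, 35."""
    active = (4, 14, 24, 34)
    values = tuple(_LASSO_VALUE * (-1.0) ** i for i in range(len(active)))
    beta = make_sparse_beta(40, active, values)
    types = ("binary",) * 20 + ("continuous",) * 20
    return beta, types


def lasso150_beta() -> tuple[np.ndarray, tuple[str, ...]]:
    """n=50, p=150 sparse design: 75 binary then 75 continuous attributes,
    7 actives among each type."""
    active = (4, 14, 24, 34, 44, 54, 64, 79, 89, 99, 109, 119, 129, 139)
    values = tuple(_LASSO_VALUE * (-1.0) ** i for i in range(len(active)))
    beta = make_sparse_beta(150, active, values)
    types = ("binary",) * 75 + ("continuous",) * 75
    return beta, types


def preset_lasso(p: int = 40, n: int = 50, seed: int | None = None) -> SimulationSpec:
    """High-dimensional sparse designs at n = 50, theta = 2."""
    if p == 40:
        beta, types = lasso40_beta()
    elif p == 150:
        beta, types = lasso150_beta()
    else:
        raise ValueError("sparse presets exist for p = 40 or p = 150")
    return SimulationSpec(n=n, theta=2.0, sigma2=3e-4, beta=tuple(beta),
                          attr_types=types, seed=seed)


PRESETS = {
    "table1": preset_table1,
    "example2": preset_example2,
    "lasso40": lambda seed=None: preset_lasso(40, seed=seed),
    "lasso150": lambda seed=None: preset_lasso(150, seed=seed),
}
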