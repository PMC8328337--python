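"""Link-prediction, variable-selection and parameter-recovery metrics.

Fitted link probabilities are posterior-predictive: the Monte-Carlo average
of p_ij over stored draws, not the probability at posterior-mean
parameters.  Prediction is evaluated in-sample against the training
adjacency.  A coefficient counts as "estimated non-zero" when its
equal-tailed credible interval excludes zero (default 95%), the standard
surrogate for exact zeros in a Bayesian shrinkage posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score, roc_curve

from .model import BETA0
from .netdata import DirectedNetwork
from .mcmc import PosteriorSamples


@dataclass
class PredictionResult:
    """Posterior-mean probability matrix against the observed adjacency."""

    probs: np.ndarray          # (n, n), diagonal ignored
    observed: np.ndarray       # (n, n) binary
    threshold: float = 0.5

    def __post_init__(self) -> None:
        P = np.asarray(self.probs, float)
        off = ~np.eye(P.shape[0], dtype=bool)
        if ((P[off] < 0) | (P[off] > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        self.probs = P
        self.observed = np.asarray(self.observed)


@dataclass
class SelectionResult:
    """Aggregated support-recovery metrics over replicates."""

    C: float                  # mean # true non-zeros kept
    IC: float                 # mean # true zeros (incorrectly) kept
    under_fit: float          # fraction of replicates missing >= 1 true non-zero
    over_fit: float           # fraction including >= 1 true zero
    correct_fit: float        # fraction with exact support recovery
    per_replicate: np.ndarray  # (R, p) inclusion flags


def posterior_mean_probs(samples: PosteriorSamples, X=None) -> np.ndarray:
    """Monte-Carlo average of p_ij across stored draws (diagonal = 0)."""
    S = samples.n_samples
    if S == 0:
        raise ValueError("no stored draws")
    n = samples.Z.shape[1]
    acc = np.zeros((n, n))
    for s in range(S):
        Z = samples.Z[s]
        D = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=-1)
        eta = BETA0 - D / samples.gamma[s][None, :]
        if X is not None and getattr(X, "p", 0):
            eta = eta + np.tensordot(samples.beta[s], X.tensor, axes=(0, 0))
        with np.errstate(over="ignore"):
            acc += 1.0 / (1.0 + np.exp(-eta))
    acc /= S
    np.fill_diagonal(acc, 0.0)
    return acc


def link_metrics(pred: PredictionResult) -> dict[str, float]:
    """TCR / TPR / FPR at the classification threshold, over ordered pairs.

    TPR is NaN when the network has no edges, FPR when it is complete.
    """
    if not 0 < pred.threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    n = pred.probs.shape[0]
    off = ~np.eye(n, dtype=bool)
    yhat = pred.probs[off] >= pred.threshold
    y = pred.observed[off].astype(bool)
    tp = int((yhat & y).sum())
    tn = int((~yhat & ~y).sum())
    fp = int((yhat & ~y).sum())
    fn = int((~yhat & y).sum())
    tcr = (tp + tn) / (n * (n - 1))
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    return {"TCR": tcr, "TPR": tpr, "FPR": fpr}


def roc_auc(pred: PredictionResult):
    """Rank-based (Mann-Whitney, midrank ties) AUC plus ROC curve points."""
    n = pred.probs.shape[0]
    off = ~np.eye(n, dtype=bool)
    y = pred.observed[off].astype(int)
    scores = pred.probs[off]
    if y.min() == y.max():
        raise ValueError("ROC needs both edge and non-edge pairs")
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    return auc, np.column_stack([fpr, tpr])


def _included(beta_chain: np.ndarray, level: float) -> np.ndarray:
    lo = np.quantile(beta_chain, level / 2, axis=0)
    hi = np.quantile(beta_chain, 1 - level / 2, axis=0)
    return (lo > 0) | (hi < 0)


def selection_metrics(beta_chains: list[np.ndarray], true_beta: np.ndarray,
                      level: float = 0.05) -> SelectionResult:
    """Support recovery across replicates.

    ``beta_chains`` holds one (S, p) array of stored coefficient draws per
    replicate; a coefficient is kept when its equal-tailed (1-level)
    credible interval excludes zero.
    """
    true_beta = np.asarray(true_beta, float)
    nonzero = true_beta != 0
    flags = np.stack([_included(ch, level) for ch in beta_chains])
    C = flags[:, nonzero].sum(axis=1)
    IC = flags[:, ~nonzero].sum(axis=1)
    under = (C < nonzero.sum()).astype(float)
    over = (IC > 0).astype(float)
    correct = ((C == nonzero.sum()) & (IC == 0)).astype(float)
    return SelectionResult(float(C.mean()), float(IC.mean()),
                           float(under.mean()), float(over.mean()),
                           float(correct.mean()), flags)


def recovery_metrics(samples: PosteriorSamples, truth: dict,
                     net: DirectedNetwork | None = None) -> dict:
    """Compare posterior means with simulation ground truth.

    Returns MSEs of pairwise latent distances and of gamma, per-edge
    estimated/true ratio samples for distances and gamma, and the Spearman
    rank correlation of posterior-mean gamma with true in-degrees (computed
    when the observed network is supplied).
    """
    Z_true = np.asarray(truth["Z"], float)
    g_true = np.asarray(truth["gamma"], float)
    n = Z_true.shape[0]
    D_true = np.linalg.norm(Z_true[:, None, :] - Z_true[None, :, :], axis=-1)
    D_hat = np.zeros((n, n))
    for s in range(samples.n_samples):
        Z = samples.Z[s]
        D_hat += np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=-1)
    D_hat /= samples.n_samples
    g_hat = samples.gamma.mean(axis=0)

    off = ~np.eye(n, dtype=bool)
    mse_dist = float(((D_hat - D_true)[off] ** 2).mean())
    mse_gamma = float(((g_hat - g_true) ** 2).mean())

    out = {"mse_dist": mse_dist, "mse_gamma": mse_gamma,
           "dist_ratios": np.array([]), "gamma_ratios": np.array([]),
           "n_zero_distance_pairs": 0, "spearman_gamma_indegree": float("nan")}
    if net is not None:
        src, dst = np.nonzero(net.adjacency)
        dt = D_true[src, dst]
        keep = dt > 0
        out["n_zero_distance_pairs"] = int((~keep).sum())
        out["dist_ratios"] = D_hat[src, dst][keep] / dt[keep]
        out["gamma_ratios"] = g_hat[dst] / g_true[dst]
        d_in = net.adjacency.sum(axis=0)
        rho = spearmanr(g_hat, d_in).statistic
        out["spearman_gamma_indegree"] = float(rho)
    return out
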