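"""Containers and statistics for directed binary networks with node attributes.

A directed network is an n x n binary adjacency matrix Y with y_ij = 1 iff
node i follows node j (no self-loops).  Node attributes, continuous or
categorical, are turned into symmetric non-negative pairwise dissimilarities
x_ij: an absolute log-ratio for continuous attributes (after column-wise
min-max normalisation into (0, 1]) and a same-category indicator for
categorical ones.  Negative regression coefficients on these covariates then
express homophily: similar nodes link more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {"source", "target", "from", "to", "src", "dst", "i", "j"}


@dataclass
class DirectedNetwork:
    """A directed binary graph: ordered node labels plus 0/1 adjacency."""

    node_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.adjacency)
        if Y.ndim != 2 or Y.shape[0] != Y.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if Y.shape[0] != len(self.node_ids):
            raise ValueError("node_ids length must match adjacency size")
        if Y.shape[0] < 2:
            raise ValueError("a directed network needs at least 2 nodes")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.diagonal(Y).any():
            raise ValueError("self-loops are not allowed (y_ii must be 0)")
        self.adjacency = Y.astype(np.int8)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


@dataclass
class AttributeTable:
    """Per-node attributes, row order matching a network's node order.

    ``types`` maps each column to ``"continuous"`` or ``"categorical"``.
    Rows with missing values are dropped up-front (with a logged warning),
    mirroring the usual preprocessing of raw social-network profiles.
    """

    data: pd.DataFrame
    types: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.types) - set(self.data.columns)
        if unknown:
            raise ValueError(f"types given for unknown columns: {sorted(unknown)}")
        bad = {c: t for c, t in self.types.items() if t not in ("continuous", "categorical")}
        if bad:
            raise ValueError(f"attribute types must be continuous/categorical, got {bad}")
        if self.data.isna().any().any():
            n_bad = int(self.data.isna().any(axis=1).sum())
            logger.warning("dropping %d attribute rows with missing values", n_bad)
            self.data = self.data.dropna()
        for col, typ in self.types.items():
            if typ == "continuous" and not np.isfinite(self.data[col].to_numpy(float)).all():
                raise ValueError(f"continuous attribute {col!r} has non-finite values")

    @property
    def node_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def p(self) -> int:
        return len(self.types)

    def aligned_to(self, node_ids: list[str]) -> "AttributeTable":
        """Reindex rows to a network's node order; error on missing nodes."""
        idx = pd.Index([str(i) for i in node_ids])
        missing = idx.difference(self.data.index.astype(str))
        if len(missing):
            raise KeyError(f"attribute rows missing for nodes: {list(missing)}")
        out = self.data.copy()
        out.index = out.index.astype(str)
        return AttributeTable(out.loc[idx], dict(self.types))


@dataclass
class PairwiseCovariates:
    """Symmetric pairwise covariates x_ij stacked as a (p, n, n) tensor.

    ``columns`` carries (source attribute name, type) metadata per covariate.
    """

    tensor: np.ndarray  # (p, n, n), diagonal meaningless
    columns: list[tuple[str, str]]

    def __post_init__(self) -> None:
        X = np.asarray(self.tensor, float)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("tensor must have shape (p, n, n)")
        if X.shape[0] != len(self.columns):
            raise ValueError("column metadata must match tensor depth")
        if (X < 0).any():
            raise ValueError("pairwise covariates must be non-negative")
        self.tensor = X

    @property
    def p(self) -> int:
        return self.tensor.shape[0]

    @property
    def n(self) -> int:
        return self.tensor.shape[1]

    @property
    def types(self) -> list[str]:
        return [t for _, t in self.columns]

    def matrix(self) -> np.ndarray:
        """Flattened (n*n, p) design matrix in row-major pair order."""
        p, n, _ = self.tensor.shape
        return self.tensor.reshape(p, n * n).T

    @classmethod
    def empty(cls, n: int) -> "PairwiseCovariates":
        return cls(np.zeros((0, n, n)), [])


@dataclass
class DegreeSummary:
    """In/out degree sequences plus the designated popular-hub index set."""

    d_in: np.ndarray
    d_out: np.ndarray
    hub_set: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.d_in = np.asarray(self.d_in, dtype=int)
        self.d_out = np.asarray(self.d_out, dtype=int)
        self.hub_set = np.asarray(self.hub_set, dtype=int)
        if self.d_in.sum() != self.d_out.sum():
            raise ValueError("in- and out-degrees must sum to the same edge count")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_network(path: str, format: str | None = None,
                 nodes: list[str] | None = None) -> DirectedNetwork:
    """Read a directed network from an edge list or a dense adjacency file.

    Edge lists are 2-column TSV/CSV (source, target), with or without a
    header; adjacency files are CSV/TSV with node ids as header row and
    first column.  Duplicate edges are collapsed; self-loops are dropped
    with a logged warning; non-binary adjacency entries raise.
    """
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if format is None:
        format = "edgelist" if raw.shape[1] == 2 else "adjacency"

    if format == "edgelist":
        if raw.shape[1] != 2:
            raise ValueError("edge list files must have exactly two columns")
        first = [str(v).strip().lower() for v in raw.iloc[0]]
        if all(v in _HEADER_TOKENS for v in first):
            raw = raw.iloc[1:]
        src = raw.iloc[:, 0].astype(str).str.strip().to_numpy()
        dst = raw.iloc[:, 1].astype(str).str.strip().to_numpy()
        if nodes is not None:
            ids = [str(v) for v in nodes]
            unknown = sorted((set(src) | set(dst)) - set(ids))
            if unknown:
                raise KeyError(f"edge references unknown node ids: {unknown}")
        else:
            ids = sorted(set(src) | set(dst))
        pos = {v: k for k, v in enumerate(ids)}
        Y = np.zeros((len(ids), len(ids)), dtype=np.int8)
        n_self = 0
        for s, t in zip(src, dst):
            if s == t:
                n_self += 1
                continue
            Y[pos[s], pos[t]] = 1
        if n_self:
            logger.warning("dropped %d self-loop edge(s)", n_self)
        return DirectedNetwork(ids, Y)

    if format == "adjacency":
        tab = pd.read_csv(path, sep=sep, index_col=0)
        ids = [str(v) for v in tab.index]
        if [str(v) for v in tab.columns] != ids:
            raise ValueError("adjacency file must have matching row/column node ids")
        Y = tab.to_numpy()
        vals = np.unique(Y)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"adjacency entries must be 0/1, found {vals[~np.isin(vals, (0, 1))]}")
        Y = Y.astype(np.int8)
        if np.diagonal(Y).any():
            logger.warning("dropped %d self-loop(s) from adjacency diagonal",
                           int(np.diagonal(Y).sum()))
            np.fill_diagonal(Y, 0)
        return DirectedNetwork(ids, Y)

    raise ValueError(f"unknown network format: {format!r}")


def read_attributes(path: str, types: dict[str, str] | None = None) -> AttributeTable:
    """Read a node-attribute CSV (first column = node id).

    Column types may be declared explicitly; otherwise numeric columns are
    treated as continuous and everything else as categorical.
    """
    tab = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    tab.index = tab.index.astype(str)
    if types is None:
        types = {c: ("continuous" if pd.api.types.is_numeric_dtype(tab[c]) else "categorical")
                 for c in tab.columns}
    return AttributeTable(tab, types)


def write_edgelist(net: DirectedNetwork, path: str) -> None:
    src, dst = np.nonzero(net.adjacency)
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for s, t in zip(src, dst):
            fh.write(f"{net.node_ids[s]}\t{net.node_ids[t]}\n")


# ---------------------------------------------------------------------------
# Degrees, covariates and empirical link statistics
# ---------------------------------------------------------------------------

def degrees(net: DirectedNetwork, n_hubs: int = 0) -> DegreeSummary:
    """Column/row degree sums plus the ``n_hubs`` largest in-degree nodes.

    Hub ties are broken towards the lower node index, deterministically.
    """
    if not 0 <= n_hubs <= net.n:
        raise ValueError("n_hubs must lie in [0, n]")
    Y = net.adjacency
    d_in = Y.sum(axis=0)
    d_out = Y.sum(axis=1)
    hubs = np.argsort(-d_in, kind="stable")[:n_hubs]
    return DegreeSummary(d_in, d_out, hubs)


def pairwise_covariates(attrs: AttributeTable, epsilon: float = 1e-3) -> PairwiseCovariates:
    """Build the symmetric pairwise design X from node attributes.

    Continuous columns are min-max rescaled to [epsilon, 1] (so the log is
    finite) and mapped to x_ij = |log a_i - log a_j|; categorical columns
    map to the indicator 1{label_i != label_j}.
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    n = len(attrs.data)
    layers, cols = [], []
    for col, typ in attrs.types.items():
        v = attrs.data[col].to_numpy()
        if typ == "continuous":
            v = v.astype(float)
            lo, hi = v.min(), v.max()
            if hi - lo == 0:
                raise ValueError(f"continuous attribute {col!r} is constant (zero range)")
            u = epsilon + (1.0 - epsilon) * (v - lo) / (hi - lo)
            lu = np.log(u)
            layers.append(np.abs(lu[:, None] - lu[None, :]))
        else:
            codes = pd.factorize(v)[0]
            layers.append((codes[:, None] != codes[None, :]).astype(float))
        cols.append((col, typ))
    tensor = np.stack(layers) if layers else np.zeros((0, n, n))
    return PairwiseCovariates(tensor, cols)


@dataclass
class LinkStats:
    """The four empirical link/reciprocity probabilities of a network.

    Conditional statistics are NaN (with the matching ``*_defined`` flag
    False) when their denominator is zero.
    """

    p_link: float
    p_mutual: float
    p_recip: float
    p_hub_recip: float
    recip_defined: bool = True
    hub_recip_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {"p_link": self.p_link, "p_mutual": self.p_mutual,
                "p_recip": self.p_recip, "p_hub_recip": self.p_hub_recip}


def empirical_link_stats(net: DirectedNetwork, degs: DegreeSummary) -> LinkStats:
    """Marginal link probability, mutual-link probability, and the two
    conditional reciprocity statistics (overall, and restricted to edges
    pointing into the designated hubs)."""
    Y = net.adjacency.astype(np.int64)
    n = net.n
    n_pairs = n * (n - 1)
    edges = Y.sum()
    mutual = (Y * Y.T).sum()
    p_link = edges / n_pairs
    p_mutual = mutual / n_pairs
    recip_defined = edges > 0
    p_recip = mutual / edges if recip_defined else float("nan")
    hubs = degs.hub_set
    if len(hubs) == 0:
        return LinkStats(p_link, p_mutual, p_recip, float("nan"),
                         recip_defined=bool(recip_defined), hub_recip_defined=False)
    into_hubs = Y[:, hubs].sum()
    hub_mutual = (Y[:, hubs] * Y.T[:, hubs]).sum()
    hub_defined = into_hubs > 0
    p_hub = hub_mutual / into_hubs if hub_defined else float("nan")
    return LinkStats(p_link, p_mutual, p_recip, p_hub,
                     recip_defined=bool(recip_defined), hub_recip_defined=bool(hub_defined))


def degree_ccdf(degs: DegreeSummary, side: str = "in",
                fit_window: tuple[float, float] | None = None):
    """Complementary CDF P(degree >= k) at each observed degree value, plus
    a least-squares log-log slope over a caller-supplied degree window.

    The window lets the caller exclude the non-linear head and noisy tail
    before fitting.  Returns ``(values, ccdf, slope)``; ``slope`` is NaN if
    no window is given.
    """
    d = degs.d_in if side == "in" else degs.d_out
    if (d == 0).all():
        raise ValueError("degree CCDF needs at least one nonzero degree")
    values, counts = np.unique(d, return_counts=True)
    # P(deg >= v): reversed cumulative count
    ccdf = counts[::-1].cumsum()[::-1] / len(d)
    slope = float("nan")
    if fit_window is not None:
        lo, hi = fit_window
        keep = (values >= lo) & (values <= hi) & (values > 0) & (ccdf > 0)
        if keep.sum() < 2:
            raise ValueError("fewer than 2 points in the CCDF fit window")
        res = _st.linregress(np.log(values[keep].astype(float)), np.log(ccdf[keep]))
        slope = float(res.slope)
    return values, ccdf, slope
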