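"""Mutual-information symptom networks over ordinal items.

Edges are the plug-in (maximum-likelihood) mutual information between item
pairs, normalized by the geometric mean of the marginal entropies so that
every weight lies in [0, 1]:

    NMI(X, Y) = [H(X) + H(Y) - H(X, Y)] / sqrt(H(X) * H(Y)).

MI captures linear and non-linear dependence alike and is exactly zero (at
the population level) iff the items are independent. No bias correction is
applied: with 4 ordinal levels and samples in the hundreds, the plug-in bias
is small relative to the edge weights of interest. Entropies use base-2
logarithms; the normalization cancels the base, so weights are
base-invariant. The graph is kept fully connected - all unordered item pairs
carry a weight, with no thresholding or sparsification.

Alternative normalizations (minimum-entropy and joint-entropy denominators)
are available through the ``norm`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .items import ITEM_IDS, N_LEVELS, subscale_of

__all__ = [
    "SymptomNetwork",
    "joint_counts",
    "entropy",
    "mutual_information",
    "normalized_mi",
    "build_network",
    "pair_codes",
    "nmi_from_pair_codes",
]

_NORMS = ("geometric", "min", "joint")


def _as_int_vector(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("expected a non-empty 1-D vector")
    return arr.astype(np.int64)


def joint_counts(x, y, n_levels: int = N_LEVELS) -> np.ndarray:
    """Contingency table of two ordinal vectors (default 4x4).

    Values must lie in {0, ..., n_levels-1}; counts sum to the sample size.
    """
    xv, yv = _as_int_vector(x), _as_int_vector(y)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.min() < 0 or xv.max() >= n_levels or yv.min() < 0 or yv.max() >= n_levels:
        raise ValueError(f"values must lie in 0..{n_levels - 1}")
    flat = np.bincount(xv * n_levels + yv, minlength=n_levels * n_levels)
    return flat.reshape(n_levels, n_levels)


def entropy(counts) -> float:
    """Plug-in Shannon entropy in bits of a count vector/table.

    0 * log 0 is treated as 0. Raises on all-zero or negative counts.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("counts must have a positive total")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def mutual_information(x, y, n_levels: int = N_LEVELS) -> float:
    """Plug-in mutual information in bits: H(X) + H(Y) - H(X, Y)."""
    table = joint_counts(x, y, n_levels=n_levels)
    return entropy(table.sum(axis=1)) + entropy(table.sum(axis=0)) - entropy(table)


def normalized_mi(x, y, n_levels: int = N_LEVELS, norm: str = "geometric") -> float:
    """Normalized mutual information in [0, 1].

    Returns 0 by convention when either margin is constant (zero entropy).
    The result is clipped to [0, 1] against floating-point error.
    """
    table = joint_counts(x, y, n_levels=n_levels)
    hx, hy = entropy(table.sum(axis=1)), entropy(table.sum(axis=0))
    if hx == 0.0 or hy == 0.0:
        return 0.0
    hxy = entropy(table)
    mi = hx + hy - hxy
    if norm == "joint":
        denom = hxy
    else:
        denom = _nmi_denominator(np.array([hx]), np.array([hy]), norm)[0]
    return float(np.clip(mi / denom, 0.0, 1.0))


def _nmi_denominator(hx: np.ndarray, hy: np.ndarray, norm: str) -> np.ndarray:
    if norm == "geometric":
        return np.sqrt(hx * hy)
    if norm == "min":
        return np.minimum(hx, hy)
    raise ValueError(f"unknown norm {norm!r}; choose from {_NORMS}")


@dataclass
class SymptomNetwork:
    """Weighted, undirected, fully connected item network.

    ``matrix`` is the symmetric node-by-node weight matrix with a zero
    diagonal (self-edges are undefined and stored as 0).
    """

    nodes: tuple[str, ...]
    matrix: np.ndarray
    sample_size: int
    group_label: str = ""
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.nodes)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match node count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("weight matrix must be symmetric")
        if (self.matrix < -1e-12).any() or (self.matrix > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")
        np.fill_diagonal(self.matrix, 0.0)
        self._index = {node: k for k, node in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def weight(self, i: str, j: str) -> float:
        """Edge weight between two distinct nodes."""
        if i == j:
            raise ValueError("self-edges are undefined")
        return float(self.matrix[self._index[i], self._index[j]])

    def edge_list(self) -> pd.DataFrame:
        """All unordered node pairs as a tidy (node_i, node_j, weight) frame."""
        rows = [
            (self.nodes[a], self.nodes[b], self.matrix[a, b])
            for a in range(self.n_nodes)
            for b in range(a + 1, self.n_nodes)
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_networkx(self, partition: dict[str, int] | None = None) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            attrs = {}
            if node in ITEM_IDS:
                attrs["subscale"] = subscale_of(node)
            if partition is not None:
                attrs["community"] = int(partition[node])
            g.add_node(node, **attrs)
        for a in range(self.n_nodes):
            for b in range(a + 1, self.n_nodes):
                g.add_edge(self.nodes[a], self.nodes[b], weight=float(self.matrix[a, b]))
        return g

    def write_edgelist(self, path: str) -> None:
        self.edge_list().to_csv(path, index=False)

    def write_graphml(self, path: str, partition: dict[str, int] | None = None) -> None:
        nx.write_graphml(self.to_networkx(partition=partition), path)

    @classmethod
    def read_edgelist(
        cls, path: str, sample_size: int = 0, group_label: str = ""
    ) -> "SymptomNetwork":
        frame = pd.read_csv(path)
        # preserve first-appearance order across both columns
        seen: dict[str, None] = {}
        for col in ("node_i", "node_j"):
            for node in frame[col]:
                seen.setdefault(node, None)
        nodes = tuple(seen)
        idx = {node: k for k, node in enumerate(nodes)}
        mat = np.zeros((len(nodes), len(nodes)))
        for _, row in frame.iterrows():
            a, b = idx[row["node_i"]], idx[row["node_j"]]
            mat[a, b] = mat[b, a] = row["weight"]
        return cls(nodes=nodes, matrix=mat, sample_size=sample_size,
                   group_label=group_label)


def pair_codes(X: np.ndarray, n_levels: int = N_LEVELS) -> np.ndarray:
    """Joint category codes for every unordered column pair.

    For a participant-by-item integer matrix with p columns, returns an
    (n, p*(p-1)/2) matrix whose column for pair (a, b) holds
    ``X[:, a] * n_levels + X[:, b]``. Permutation tests reuse these codes to
    re-estimate all pairwise tables with a single ``bincount`` per draw.
    """
    X = np.asarray(X, dtype=np.int64)
    a, b = np.triu_indices(X.shape[1], k=1)
    return X[:, a] * n_levels + X[:, b]


def _entropies_from_counts(counts: np.ndarray) -> np.ndarray:
    """Row-wise plug-in entropies (bits) of a (pairs, cells) count array."""
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def nmi_from_pair_codes(
    codes: np.ndarray, n_levels: int = N_LEVELS, norm: str = "geometric"
) -> np.ndarray:
    """Normalized MI for every pair from precomputed joint codes.

    Returns a vector of length p*(p-1)/2 in upper-triangle order.
    """
    n, n_pairs = codes.shape
    cells = n_levels * n_levels
    flat = codes + np.arange(n_pairs, dtype=np.int64) * cells
    counts = np.bincount(flat.ravel(), minlength=n_pairs * cells).reshape(
        n_pairs, n_levels, n_levels
    )
    hx = _entropies_from_counts(counts.sum(axis=2))
    hy = _entropies_from_counts(counts.sum(axis=1))
    hxy = _entropies_from_counts(counts.reshape(n_pairs, cells))
    mi = hx + hy - hxy
    if norm == "joint":
        denom = hxy
    else:
        denom = _nmi_denominator(hx, hy, norm)
    out = np.zeros(n_pairs)
    ok = denom > 0
    out[ok] = np.clip(mi[ok] / denom[ok], 0.0, 1.0)
    return out


def build_network(
    table: pd.DataFrame,
    items: tuple[str, ...] = ITEM_IDS,
    group_label: str | None = None,
    norm: str = "geometric",
) -> SymptomNetwork:
    """Estimate the full pairwise NMI network from a cohort table.

    All pairs are computed on the same participant set; at least 2 rows are
    required. For the 14-item catalog this yields 91 edge weights.
    """
    X = table[list(items)].to_numpy(dtype=np.int64)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 participants, got {n}")
    weights = nmi_from_pair_codes(pair_codes(X), norm=norm)
    p = len(items)
    mat = np.zeros((p, p))
    a, b = np.triu_indices(p, k=1)
    mat[a, b] = weights
    mat[b, a] = weights
    if group_label is None:
        labels = table["group"].unique() if "group" in table.columns else []
        group_label = str(labels[0]) if len(labels) == 1 else ""
    return SymptomNetwork(
        nodes=tuple(items), matrix=mat, sample_size=n, group_label=group_label
    )
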