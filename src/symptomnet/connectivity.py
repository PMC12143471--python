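"""Within/between-community connectivity and permutation inference.

Connectivity is operationalized as the mean edge weight over node pairs
inside one community (within) or spanning different communities (between).
Two permutation schemes are provided, matching the two kinds of contrast:

* **Group contrasts** (young vs. old): participants are the exchangeable
  units. The null pools the participants of both cohorts, reshuffles group
  labels preserving group sizes, rebuilds both networks per draw, and
  recomputes the statistic difference. By default each group's community
  partition is held fixed at its observed-data estimate, isolating
  connectivity differences from partition instability; re-detection per
  draw is available via ``partition_policy="redetect"``.
* **Community contrasts** (anxiety vs. depression within one network):
  nodes are the exchangeable units. The null reassigns node community
  labels at random, preserving community sizes, on the fixed network.

Both report the two-sided permutation p-value with the +1 correction,
p = (1 + #{|null| >= |observed|}) / (n_iter + 1), which is valid under
exchangeability and can never be 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import Partition, detect_communities
from .errors import ConfigurationError, UndefinedResultError
from .items import ITEM_IDS
from .network import SymptomNetwork, build_network, nmi_from_pair_codes, pair_codes

__all__ = [
    "ConnectivitySummary",
    "PermutationResult",
    "within_connectivity",
    "between_connectivity",
    "connectivity_summary",
    "permutation_test_groups",
    "permutation_test_communities",
]

DEFAULT_N_ITER = 5000


@dataclass(frozen=True)
class ConnectivitySummary:
    """Mean edge weights (and pair counts) for one network under one partition."""

    within: dict[int, float]
    within_pairs: dict[int, int]
    between: float
    between_pairs: int
    between_by_community: dict[int, float]
    group_label: str = ""


@dataclass
class PermutationResult:
    statistic_name: str
    observed_diff: float
    observed_values: tuple[float, float]
    null_diffs: np.ndarray
    p_value: float
    n_iter: int
    seed: int

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "statistic": self.statistic_name,
            "observed_diff": self.observed_diff,
            "observed_values": list(self.observed_values),
            "p_value": self.p_value,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }
        if include_null:
            out["null_diffs"] = self.null_diffs.tolist()
        return out


def _permutation_p(null_diffs: np.ndarray, observed: float) -> float:
    return float((1 + (np.abs(null_diffs) >= abs(observed)).sum())
                 / (len(null_diffs) + 1))


def _upper_weights(network: SymptomNetwork) -> np.ndarray:
    a, b = np.triu_indices(network.n_nodes, k=1)
    return network.matrix[a, b]


def _within_mask(labels: np.ndarray, community: int) -> np.ndarray:
    a, b = np.triu_indices(len(labels), k=1)
    return (labels[a] == community) & (labels[b] == community)


def _between_mask(labels: np.ndarray, community: int | None = None) -> np.ndarray:
    a, b = np.triu_indices(len(labels), k=1)
    mask = labels[a] != labels[b]
    if community is not None:
        mask &= (labels[a] == community) | (labels[b] == community)
    return mask


def within_connectivity(
    network: SymptomNetwork, partition: Partition, community: int
) -> float:
    """Mean edge weight over all unordered pairs inside one community."""
    labels = partition.labels_for(network.nodes)
    mask = _within_mask(labels, community)
    if not mask.any():
        raise UndefinedResultError(
            f"community {community} has fewer than 2 nodes; no within pairs"
        )
    return float(_upper_weights(network)[mask].mean())


def between_connectivity(
    network: SymptomNetwork, partition: Partition, community: int | None = None
) -> float:
    """Mean edge weight over pairs spanning different communities.

    With ``community`` given, restricts to cross-community pairs incident to
    that community.
    """
    if partition.n_communities < 2:
        raise UndefinedResultError("between-connectivity needs >= 2 communities")
    labels = partition.labels_for(network.nodes)
    mask = _between_mask(labels, community)
    return float(_upper_weights(network)[mask].mean())


def connectivity_summary(
    network: SymptomNetwork, partition: Partition
) -> ConnectivitySummary:
    """Within means per community plus overall and per-community between means."""
    labels = partition.labels_for(network.nodes)
    w = _upper_weights(network)
    within, within_pairs, between_by = {}, {}, {}
    for c in range(partition.n_communities):
        mask = _within_mask(labels, c)
        if mask.any():
            within[c] = float(w[mask].mean())
            within_pairs[c] = int(mask.sum())
    if partition.n_communities >= 2:
        bmask = _between_mask(labels)
        between = float(w[bmask].mean())
        between_pairs = int(bmask.sum())
        for c in range(partition.n_communities):
            between_by[c] = float(w[_between_mask(labels, c)].mean())
    else:
        between, between_pairs = float("nan"), 0
    return ConnectivitySummary(
        within=within, within_pairs=within_pairs, between=between,
        between_pairs=between_pairs, between_by_community=between_by,
        group_label=network.group_label,
    )


def _stat_from_weights(
    weights: np.ndarray, labels: np.ndarray, kind: str, community: int | None
) -> float:
    if kind == "within":
        if community is None:
            raise ConfigurationError("within statistic needs a community id")
        mask = _within_mask(labels, community)
        if not mask.any():
            raise UndefinedResultError(f"community {community} has no within pairs")
    elif kind == "between":
        mask = _between_mask(labels, community)
        if not mask.any():
            raise UndefinedResultError("partition has no between pairs")
    else:
        raise ConfigurationError(f"unknown statistic kind {kind!r}")
    return float(weights[mask].mean())


def _matched_community(partition: Partition, nodes, reference_nodes: set[str]) -> int:
    """Community of `partition` with maximal overlap with a reference node set."""
    overlap = {
        c: len(set(partition.community(c)) & reference_nodes)
        for c in range(partition.n_communities)
    }
    return max(sorted(overlap), key=overlap.get)


def permutation_test_groups(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    kind: str,
    partition_a: Partition,
    partition_b: Partition,
    community_a: int | None = None,
    community_b: int | None = None,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    partition_policy: str = "fixed",
    redetect_restarts: int = 10,
    items: tuple[str, ...] = ITEM_IDS,
    statistic_name: str | None = None,
) -> PermutationResult:
    """Permutation test of a connectivity difference between two cohorts.

    ``kind`` is ``"within"`` (requires per-group community ids) or
    ``"between"`` (optionally restricted per group). The observed statistic
    is stat(A) - stat(B); the null reshuffles participants between groups.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both cohorts must be non-empty")
    if partition_policy not in ("fixed", "redetect"):
        raise ConfigurationError(f"unknown partition_policy {partition_policy!r}")

    xa = table_a[list(items)].to_numpy(dtype=np.int64)
    xb = table_b[list(items)].to_numpy(dtype=np.int64)
    na = xa.shape[0]
    labels_a = partition_a.labels_for(items)
    labels_b = partition_b.labels_for(items)

    wa = nmi_from_pair_codes(pair_codes(xa))
    wb = nmi_from_pair_codes(pair_codes(xb))
    obs_a = _stat_from_weights(wa, labels_a, kind, community_a)
    obs_b = _stat_from_weights(wb, labels_b, kind, community_b)
    observed = obs_a - obs_b

    pooled_codes = pair_codes(np.vstack([xa, xb]))
    n_total = pooled_codes.shape[0]
    rng = np.random.default_rng(seed)
    ref_a = set(partition_a.community(community_a)) if community_a is not None else None
    ref_b = set(partition_b.community(community_b)) if community_b is not None else None

    null = np.empty(n_iter)
    for it in range(n_iter):
        perm = rng.permutation(n_total)
        w1 = nmi_from_pair_codes(pooled_codes[perm[:na]])
        w2 = nmi_from_pair_codes(pooled_codes[perm[na:]])
        if partition_policy == "fixed":
            s1 = _stat_from_weights(w1, labels_a, kind, community_a)
            s2 = _stat_from_weights(w2, labels_b, kind, community_b)
        else:
            s1 = _redetected_stat(w1, items, kind, ref_a, rng, redetect_restarts)
            s2 = _redetected_stat(w2, items, kind, ref_b, rng, redetect_restarts)
        null[it] = s1 - s2

    name = statistic_name or _default_name(kind, community_a, community_b)
    return PermutationResult(
        statistic_name=name, observed_diff=observed,
        observed_values=(obs_a, obs_b), null_diffs=null,
        p_value=_permutation_p(null, observed), n_iter=n_iter, seed=seed,
    )


def _redetected_stat(weights, items, kind, reference, rng, n_restarts) -> float:
    p = len(items)
    mat = np.zeros((p, p))
    a, b = np.triu_indices(p, k=1)
    mat[a, b] = weights
    mat[b, a] = weights
    net = SymptomNetwork(nodes=tuple(items), matrix=mat, sample_size=0)
    part = detect_communities(net, seed=int(rng.integers(2**31)),
                              n_restarts=n_restarts)
    community = None
    if reference is not None:
        community = _matched_community(part, items, reference)
    return _stat_from_weights(weights, part.labels_for(items), kind, community)


def _default_name(kind, community_a, community_b) -> str:
    if kind == "within":
        return f"within[{community_a}|{community_b}]"
    if community_a is None and community_b is None:
        return "between"
    return f"between[{community_a}|{community_b}]"


def permutation_test_communities(
    source: pd.DataFrame | SymptomNetwork,
    partition: Partition,
    community_a: int,
    community_b: int,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    items: tuple[str, ...] = ITEM_IDS,
    statistic_name: str | None = None,
) -> PermutationResult:
    """Permutation test of within-connectivity between two communities.

    The network is fixed; the null randomly reassigns node community labels
    preserving community sizes.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    network = source if isinstance(source, SymptomNetwork) else build_network(
        source, items=items
    )
    labels = partition.labels_for(network.nodes)
    w = _upper_weights(network)
    obs_a = _stat_from_weights(w, labels, "within", community_a)
    obs_b = _stat_from_weights(w, labels, "within", community_b)
    observed = obs_a - obs_b

    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for it in range(n_iter):
        shuffled = rng.permutation(labels)
        null[it] = (
            _stat_from_weights(w, shuffled, "within", community_a)
            - _stat_from_weights(w, shuffled, "within", community_b)
        )
    name = statistic_name or f"within[{community_a}]-within[{community_b}]"
    return PermutationResult(
        statistic_name=name, observed_diff=observed,
        observed_values=(obs_a, obs_b), null_diffs=null,
        p_value=_permutation_p(null, observed), n_iter=n_iter, seed=seed,
    )
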