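"""Strength-based centrality for fully connected symptom networks.

Strength centrality is a node's total incident edge weight; bridge strength
is its incident weight to nodes in *other* communities, so a node's
strength decomposes exactly into within-community strength plus bridge
strength. Only strength-based metrics are provided: path-based centralities
(betweenness, closeness) are ill-suited to fully connected weighted graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .communities import Partition
from .errors import UndefinedResultError
from .network import SymptomNetwork

__all__ = [
    "CentralityProfile",
    "strength_centrality",
    "bridge_strength",
    "rank_centrality",
    "top_node",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CentralityProfile:
    """Per-node strength (and, when a partition is given, its decomposition)."""

    nodes: tuple[str, ...]
    strength: np.ndarray
    within_strength: np.ndarray | None = None
    bridge_strength: np.ndarray | None = None
    group_label: str = ""

    def values(self, field: str) -> np.ndarray:
        out = getattr(self, "strength" if field == "strength" else f"{field}_strength")
        if out is None:
            raise UndefinedResultError(
                f"profile carries no {field!r} values (no partition supplied)"
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"node": self.nodes, "strength": self.strength})
        if self.within_strength is not None:
            frame["within_strength"] = self.within_strength
            frame["bridge_strength"] = self.bridge_strength
        frame["group"] = self.group_label
        return frame


def strength_centrality(network: SymptomNetwork) -> CentralityProfile:
    """Sum of each node's incident edge weights."""
    return CentralityProfile(
        nodes=network.nodes,
        strength=network.matrix.sum(axis=1),
        group_label=network.group_label,
    )


def bridge_strength(network: SymptomNetwork, partition: Partition) -> CentralityProfile:
    """Strength decomposition relative to a partition.

    ``bridge_strength[i]`` sums i's weights to nodes outside its community;
    ``within_strength[i]`` the rest, so strength = within + bridge exactly.
    A single-community partition yields all-zero bridge strength (warned).
    """
    labels = partition.labels_for(network.nodes)
    if partition.n_communities < 2:
        logger.warning("single-community partition: bridge strength is zero everywhere")
    same = labels[:, None] == labels[None, :]
    within = (network.matrix * same).sum(axis=1)
    bridge = (network.matrix * ~same).sum(axis=1)
    return CentralityProfile(
        nodes=network.nodes,
        strength=network.matrix.sum(axis=1),
        within_strength=within,
        bridge_strength=bridge,
        group_label=network.group_label,
    )


def rank_centrality(
    profile_a: CentralityProfile,
    profile_b: CentralityProfile,
    field: str = "strength",
    method: str = "t",
) -> tuple[float, float]:
    """Spearman rank correlation of two centrality profiles.

    Ranks use midranks for ties. ``method="t"`` gives the two-sided p from
    the t approximation; ``method="exact"`` uses a permutation distribution
    (exact for small n, Monte Carlo otherwise) - useful below n ~ 10.
    """
    if set(profile_a.nodes) != set(profile_b.nodes):
        raise ValueError("profiles cover different node sets")
    order = list(profile_a.nodes)
    xa = profile_a.values(field)
    xb = profile_b.values(field)[[profile_b.nodes.index(n) for n in order]]
    if np.ptp(stats.rankdata(xa)) == 0 or np.ptp(stats.rankdata(xb)) == 0:
        raise UndefinedResultError("constant ranking: Spearman rho undefined")
    if method == "t":
        res = stats.spearmanr(xa, xb)
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        rho = float(stats.spearmanr(xa, xb).statistic)
        perm = stats.permutation_test(
            (xa, xb),
            lambda x, y: stats.spearmanr(x, y).statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=100_000,
            random_state=0,
        )
        return rho, float(perm.pvalue)
    raise ValueError(f"unknown method {method!r}")


def top_node(profile: CentralityProfile, field: str = "strength") -> str:
    """Node with the highest value; ties broken by item-id order."""
    values = profile.values(field)
    max_val = values.max()
    winners = [n for n, v in zip(profile.nodes, values) if v == max_val]
    return min(winners)
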