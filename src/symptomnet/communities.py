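"""Community detection on symptom networks.

Communities (symptom clusters) are found by weighted-modularity maximization
with the Louvain heuristic. Louvain's result depends on node visiting order,
so :func:`detect_communities` runs many restarts from seed-derived orders
and keeps the partition with the highest modularity, making the outcome a
deterministic function of (network, seed, n_restarts). The fixed HADS
partition (anxiety vs. depression items) is provided for validation
analyses that bypass data-driven clustering.

Community labels are canonicalized by order of each community's lowest node
index, so label 0 always contains the first node of the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from networkx.algorithms.community import louvain_communities
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigurationError
from .items import ANXIETY, ITEM_IDS, subscale_of
from .network import SymptomNetwork

__all__ = [
    "Partition",
    "modularity",
    "modularity_from_matrix",
    "detect_communities",
    "fixed_hads_partition",
    "compare_partitions",
]


@dataclass(frozen=True)
class Partition:
    """Node-to-community assignment with its modularity on the source network."""

    assignment: dict[str, int]
    method: str = "louvain"
    modularity_q: float | None = None

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if labels != set(range(len(labels))):
            raise ValueError("community ids must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    def community(self, label: int) -> tuple[str, ...]:
        return tuple(n for n, c in self.assignment.items() if c == label)

    def labels_for(self, nodes) -> np.ndarray:
        return np.array([self.assignment[n] for n in nodes])


def canonicalize(assignment: dict[str, int], nodes) -> dict[str, int]:
    """Relabel communities 0,1,... by order of their lowest node index."""
    order: dict[int, int] = {}
    for node in nodes:
        c = assignment[node]
        if c not in order:
            order[c] = len(order)
    return {node: order[assignment[node]] for node in nodes}


def modularity_from_matrix(W: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman-Girvan modularity of a labeled weight matrix.

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] * delta(c_i, c_j), with the
    diagonal of A ignored (no self-loops) and resolution 1.
    """
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    k = W.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0:
        raise ValueError("network has no edge weight")
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(((W - np.outer(k, k) / two_m) * same).sum() / two_m)


def modularity(network: SymptomNetwork, partition: Partition) -> float:
    """Modularity Q of a partition on a symptom network."""
    missing = [n for n in network.nodes if n not in partition.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing}")
    return modularity_from_matrix(network.matrix, partition.labels_for(network.nodes))


def detect_communities(
    network: SymptomNetwork,
    seed: int = 0,
    n_restarts: int = 100,
    resolution: float = 1.0,
) -> Partition:
    """Best-of-restarts Louvain partition of a symptom network.

    Runs the Louvain local-moving + aggregation heuristic ``n_restarts``
    times with restart seeds spawned from ``seed`` and returns the partition
    with maximal modularity (ties broken by first occurrence), with labels
    canonicalized by lowest node index.
    """
    if n_restarts < 1:
        raise ConfigurationError("n_restarts must be >= 1")
    g = network.to_networkx()
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best_q, best_assignment = -np.inf, None
    for s in restart_seeds:
        comms = louvain_communities(g, weight="weight", resolution=resolution,
                                    seed=int(s))
        assignment = {n: c for c, nodes in enumerate(comms) for n in nodes}
        q = modularity_from_matrix(
            network.matrix, np.array([assignment[n] for n in network.nodes])
        )
        if q > best_q + 1e-15:
            best_q, best_assignment = q, assignment
    assignment = canonicalize(best_assignment, network.nodes)
    return Partition(assignment=assignment, method="louvain",
                     modularity_q=float(best_q))


def fixed_hads_partition(items: tuple[str, ...] = ITEM_IDS) -> Partition:
    """The a-priori HADS split: anxiety items vs. depression items."""
    assignment = {i: (0 if subscale_of(i) == ANXIETY else 1) for i in items}
    return Partition(assignment=canonicalize(assignment, items), method="fixed_hads")


def compare_partitions(p1: Partition, p2: Partition) -> float:
    """Adjusted Rand index between two partitions of the same node set."""
    if set(p1.assignment) != set(p2.assignment):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(p1.assignment)
    return float(adjusted_rand_score(p1.labels_for(nodes), p2.labels_for(nodes)))
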