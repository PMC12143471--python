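"""End-to-end study orchestration.

``run_study`` executes the full replication pipeline - simulate or load a
cohort, apply the subclinical inclusion filter, split age groups, estimate
the per-group mutual-information networks, detect communities, compute
within/between-community connectivity with permutation inference, centrality
profiles and rank comparisons, and the descriptive comparison tables - and
returns a serializable :class:`StudyReport`. The report's JSON schema is
published at ``schemas/study_report.schema.json``.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import __version__
from .centrality import bridge_strength, rank_centrality, top_node
from .cohort import (
    assign_age_groups,
    filter_subclinical,
    read_cohort,
    score_hads,
    write_cohort,
)
from .communities import (
    Partition,
    compare_partitions,
    detect_communities,
    fixed_hads_partition,
    modularity,
)
from .connectivity import (
    connectivity_summary,
    permutation_test_communities,
    permutation_test_groups,
)
from .errors import ConfigurationError
from .items import ANXIETY_ITEMS, DEPRESSION_ITEMS, ITEM_IDS
from .network import SymptomNetwork, build_network
from .simulate import (
    SyntheticConfig,
    generate_cohort,
    old_default_config,
    young_default_config,
)
from .stats import compare_item_severity, cronbach_alpha, group_characteristics

logger = logging.getLogger(__name__)

SMALL_GROUP_WARNING_N = 100  # network estimates become unstable below this


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode is active: ``"simulate"`` generates cohorts from
    ``simulate_configs`` (defaults used when None), ``"load"`` reads a
    cohort CSV from ``input_path`` and derives age groups from the age
    column.
    """

    mode: str = "simulate"
    input_path: str | None = None
    simulate_configs: dict[str, SyntheticConfig] | None = None
    group_labels: tuple[str, str] = ("young", "old")
    min_hads_d: int = 4
    partition_policy: str = "data_driven"  # or "fixed_hads"
    n_iter: int = 5000
    permutation_seed: int = 11
    louvain_seed: int = 7
    louvain_restarts: int = 100
    base_seed: int = 2026
    output_dir: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "load" and not self.input_path:
            raise ConfigurationError("load mode requires input_path")
        if self.partition_policy not in ("data_driven", "fixed_hads"):
            raise ConfigurationError(
                f"unknown partition_policy {self.partition_policy!r}"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "group_labels" in raw:
            raw["group_labels"] = tuple(raw["group_labels"])
        return cls(**raw)

    def canonical_dict(self) -> dict:
        cfgs = None
        if self.simulate_configs is not None:
            cfgs = {
                label: {
                    "n_participants": c.n_participants,
                    "loadings": dict(sorted(c.loadings.items())),
                    "thresholds": {k: list(v) for k, v in sorted(c.thresholds.items())},
                    "factor_correlation": c.factor_correlation,
                    "age_range": list(c.age_range),
                    "seed": c.seed,
                }
                for label, c in self.simulate_configs.items()
            }
        return {
            "mode": self.mode,
            "input_path": self.input_path,
            "simulate_configs": cfgs,
            "group_labels": list(self.group_labels),
            "min_hads_d": self.min_hads_d,
            "partition_policy": self.partition_policy,
            "n_iter": self.n_iter,
            "permutation_seed": self.permutation_seed,
            "louvain_seed": self.louvain_seed,
            "louvain_restarts": self.louvain_restarts,
            "base_seed": self.base_seed,
        }

    def hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# report models


class PartitionReport(BaseModel):
    method: str
    n_communities: int
    modularity_q: float | None
    assignment: dict[str, int]


class ConnectivityReport(BaseModel):
    within: dict[str, float]
    within_pairs: dict[str, int]
    between: float
    between_pairs: int
    between_by_community: dict[str, float]


class GroupReport(BaseModel):
    label: str
    n_participants: int
    edges: dict[str, float]
    partition: PartitionReport
    connectivity: ConnectivityReport
    centrality: dict[str, dict[str, float]]
    cronbach_alpha: dict[str, float]
    top_strength_node: str
    top_bridge_node: str
    anxiety_community: int
    depression_community: int


class PermutationReport(BaseModel):
    statistic: str
    contrast: str
    observed_diff: float
    observed_values: list[float]
    p_value: float
    n_iter: int
    seed: int


class RankCorrelationReport(BaseModel):
    field: str
    rho: float
    p_value: float


class Provenance(BaseModel):
    config_hash: str
    package_version: str
    seeds: dict[str, int]
    n_rows_input: int
    n_rows_included: int
    generated_at: str


class StudyReport(BaseModel):
    groups: dict[str, GroupReport]
    permutation_tests: list[PermutationReport]
    rank_correlations: list[RankCorrelationReport]
    group_characteristics: list[dict]
    item_comparisons: list[dict]
    partition_agreement_between_groups: float
    provenance: Provenance

    def network_for(self, label: str) -> SymptomNetwork:
        """Rebuild a group's symptom network from the serialized edges."""
        g = self.groups[label]
        mat = np.zeros((len(ITEM_IDS), len(ITEM_IDS)))
        idx = {n: k for k, n in enumerate(ITEM_IDS)}
        for key, w in g.edges.items():
            a, b = key.split("|")
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = w
        return SymptomNetwork(
            nodes=ITEM_IDS, matrix=mat, sample_size=g.n_participants,
            group_label=label,
        )

    def partition_for(self, label: str) -> Partition:
        p = self.groups[label].partition
        return Partition(
            assignment=dict(p.assignment), method=p.method,
            modularity_q=p.modularity_q,
        )


# ---------------------------------------------------------------------------
# helpers


def _records(frame: pd.DataFrame) -> list[dict]:
    """DataFrame rows as JSON-safe dicts (missing cells become None)."""
    return frame.astype(object).where(frame.notna(), None).to_dict(orient="records")


def majority_community(partition: Partition, item_set) -> int:
    """Community holding the largest share of a given item set (ties: lowest id)."""
    counts = {
        c: len(set(partition.community(c)) & set(item_set))
        for c in range(partition.n_communities)
    }
    best = max(counts.values())
    return min(c for c, v in counts.items() if v == best)


def _edges_dict(network: SymptomNetwork) -> dict[str, float]:
    frame = network.edge_list()
    return {
        f"{r.node_i}|{r.node_j}": float(r.weight) for r in frame.itertuples()
    }


def _group_report(
    label: str, table: pd.DataFrame, config: RunConfig
) -> tuple[GroupReport, SymptomNetwork, Partition]:
    if len(table) < SMALL_GROUP_WARNING_N:
        logger.warning(
            "group %s has only %d participants; network estimates are unstable",
            label, len(table),
        )
    network = build_network(table, group_label=label)
    if config.partition_policy == "fixed_hads":
        partition = fixed_hads_partition()
        partition = Partition(
            assignment=partition.assignment, method="fixed_hads",
            modularity_q=modularity(network, partition),
        )
    else:
        partition = detect_communities(
            network, seed=config.louvain_seed, n_restarts=config.louvain_restarts
        )
    summary = connectivity_summary(network, partition)
    profile = bridge_strength(network, partition)
    anx_c = majority_community(partition, ANXIETY_ITEMS)
    dep_c = majority_community(partition, DEPRESSION_ITEMS)
    report = GroupReport(
        label=label,
        n_participants=len(table),
        edges=_edges_dict(network),
        partition=PartitionReport(
            method=partition.method,
            n_communities=partition.n_communities,
            modularity_q=partition.modularity_q,
            assignment=dict(partition.assignment),
        ),
        connectivity=ConnectivityReport(
            within={str(k): v for k, v in summary.within.items()},
            within_pairs={str(k): v for k, v in summary.within_pairs.items()},
            between=summary.between,
            between_pairs=summary.between_pairs,
            between_by_community={
                str(k): v for k, v in summary.between_by_community.items()
            },
        ),
        centrality={
            node: {
                "strength": float(profile.strength[k]),
                "within_strength": float(profile.within_strength[k]),
                "bridge_strength": float(profile.bridge_strength[k]),
            }
            for k, node in enumerate(profile.nodes)
        },
        cronbach_alpha={
            "anxiety": cronbach_alpha(table[list(ANXIETY_ITEMS)]),
            "depression": cronbach_alpha(table[list(DEPRESSION_ITEMS)]),
        },
        top_strength_node=top_node(profile, "strength"),
        top_bridge_node=top_node(profile, "bridge"),
        anxiety_community=anx_c,
        depression_community=dep_c,
    )
    return report, network, partition


# ---------------------------------------------------------------------------
# pipeline


def acquire_cohort(config: RunConfig) -> pd.DataFrame:
    """Stage 1: simulate or load the raw cohort table."""
    if config.mode == "simulate":
        cfgs = config.simulate_configs
        if cfgs is None:
            cfgs = {
                config.group_labels[0]: young_default_config(seed=config.base_seed),
                config.group_labels[1]: old_default_config(seed=config.base_seed + 1),
            }
        labels = list(cfgs)
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate group labels in simulate_configs")
        return pd.concat(
            [generate_cohort(c) for c in cfgs.values()], ignore_index=True
        )
    table = read_cohort(config.input_path)
    return assign_age_groups(table)


def run_study(config: RunConfig) -> StudyReport:
    """Execute the whole pipeline and return the consolidated report.

    Idempotent given the seeds in ``config``: two runs with the same config
    produce identical reports except for the ``generated_at`` stamp. When
    ``config.output_dir`` is set, edge lists, GraphML, partition, centrality
    and descriptive CSVs plus the JSON report are written there.
    """
    raw = acquire_cohort(config)
    logger.info("stage cohort: %d rows", len(raw))
    included = filter_subclinical(raw, config.min_hads_d)
    logger.info("stage filter: %d rows retained", len(included))

    g1, g2 = config.group_labels
    tables = {g: included[included["group"] == g].reset_index(drop=True)
              for g in (g1, g2)}
    for g, t in tables.items():
        if len(t) == 0:
            raise ValueError(f"group {g!r} is empty after filtering")

    groups: dict[str, GroupReport] = {}
    networks: dict[str, SymptomNetwork] = {}
    partitions: dict[str, Partition] = {}
    for g in (g1, g2):
        groups[g], networks[g], partitions[g] = _group_report(g, tables[g], config)
        logger.info(
            "stage network[%s]: n=%d, %d communities, Q=%.4f",
            g, len(tables[g]), partitions[g].n_communities,
            partitions[g].modularity_q or float("nan"),
        )

    # --- permutation inference ------------------------------------------------
    perms: list[PermutationReport] = []
    seed = config.permutation_seed
    contrasts = [
        ("within_anxiety_age_contrast", "within",
         groups[g1].anxiety_community, groups[g2].anxiety_community),
        ("within_depression_age_contrast", "within",
         groups[g1].depression_community, groups[g2].depression_community),
        ("between_community_age_contrast", "between", None, None),
    ]
    for k, (name, kind, ca, cb) in enumerate(contrasts):
        try:
            res = permutation_test_groups(
                tables[g1], tables[g2], kind=kind,
                partition_a=partitions[g1], partition_b=partitions[g2],
                community_a=ca, community_b=cb,
                n_iter=config.n_iter, seed=seed + k,
                partition_policy="fixed",
            )
        except Exception:
            logger.exception("stage permutation[%s] failed", name)
            raise
        perms.append(
            PermutationReport(
                statistic=res.statistic_name, contrast=name,
                observed_diff=res.observed_diff,
                observed_values=list(res.observed_values),
                p_value=res.p_value, n_iter=res.n_iter, seed=res.seed,
            )
        )
    for k, g in enumerate((g1, g2)):
        res = permutation_test_communities(
            networks[g], partitions[g],
            community_a=groups[g].anxiety_community,
            community_b=groups[g].depression_community,
            n_iter=config.n_iter, seed=seed + 100 + k,
        )
        perms.append(
            PermutationReport(
                statistic=res.statistic_name,
                contrast=f"anxiety_vs_depression_within_{g}",
                observed_diff=res.observed_diff,
                observed_values=list(res.observed_values),
                p_value=res.p_value, n_iter=res.n_iter, seed=res.seed,
            )
        )

    # --- centrality rank comparisons -----------------------------------------
    prof = {g: bridge_strength(networks[g], partitions[g]) for g in (g1, g2)}
    ranks = []
    for fld in ("strength", "bridge"):
        rho, p = rank_centrality(prof[g1], prof[g2], field=fld)
        ranks.append(RankCorrelationReport(field=fld, rho=rho, p_value=p))

    # --- descriptives ---------------------------------------------------------
    both = pd.concat([tables[g1], tables[g2]], ignore_index=True)
    characteristics = group_characteristics(both, score_hads(both))
    item_cmp = compare_item_severity(both)

    report = StudyReport(
        groups=groups,
        permutation_tests=perms,
        rank_correlations=ranks,
        group_characteristics=_records(characteristics),
        item_comparisons=_records(item_cmp),
        partition_agreement_between_groups=compare_partitions(
            partitions[g1], partitions[g2]
        ),
        provenance=Provenance(
            config_hash=config.hash(),
            package_version=__version__,
            seeds={
                "permutation": config.permutation_seed,
                "louvain": config.louvain_seed,
                "base": config.base_seed,
            },
            n_rows_input=len(raw),
            n_rows_included=len(included),
            generated_at=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        ),
    )

    if config.output_dir:
        _write_outputs(config, report, tables, networks, partitions,
                       characteristics, item_cmp)
    return report


def _write_outputs(config, report, tables, networks, partitions,
                   characteristics, item_cmp) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    for g, net in networks.items():
        net.edge_list().to_csv(out / f"edges_{g}.csv", index=False,
                               float_format=fmt)
        net.write_graphml(out / f"network_{g}.graphml",
                          partition=partitions[g].assignment)
        part = pd.DataFrame(
            {
                "node": list(partitions[g].assignment),
                "community": list(partitions[g].assignment.values()),
                "method": partitions[g].method,
            }
        )
        part.to_csv(out / f"partition_{g}.csv", index=False)
        cent = bridge_strength(net, partitions[g]).to_frame()
        cent.to_csv(out / f"centrality_{g}.csv", index=False, float_format=fmt)
        write_cohort(tables[g], out / f"cohort_{g}.csv")
    characteristics.to_csv(out / "group_characteristics.csv", index=False,
                           float_format=fmt)
    item_cmp.to_csv(out / "item_comparisons.csv", index=False, float_format=fmt)
    with open(out / "report.json", "w") as fh:
        fh.write(report.model_dump_json(indent=2))
    logger.info("outputs written to %s", out)


def validate_fixed_partition(report: StudyReport) -> pd.DataFrame:
    """Recompute connectivity and bridge metrics under the fixed HADS split.

    For each group, tabulates within/between connectivity and the top bridge
    node under the report's data-driven partition and under the a-priori
    anxiety/depression partition, plus the ARI between the two partitions.
    """
    fixed = fixed_hads_partition()
    rows = []
    for label in report.groups:
        net = report.network_for(label)
        data_part = report.partition_for(label)
        for name, part in (("data_driven", data_part), ("fixed_hads", fixed)):
            summary = connectivity_summary(net, part)
            prof = bridge_strength(net, part)
            anx_c = majority_community(part, ANXIETY_ITEMS)
            dep_c = majority_community(part, DEPRESSION_ITEMS)
            rows.append(
                {
                    "group": label,
                    "partition": name,
                    "n_communities": part.n_communities,
                    "within_anxiety": summary.within.get(anx_c, float("nan")),
                    "within_depression": summary.within.get(dep_c, float("nan")),
                    "between": summary.between,
                    "top_bridge_node": top_node(prof, "bridge"),
                    "ari_vs_data_driven": compare_partitions(part, data_part),
                }
            )
    return pd.DataFrame(rows)
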