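"""Connectivity summaries and permutation inference."""

import itertools

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.communities import Partition
from symptomnet.errors import ConfigurationError, UndefinedResultError

from .conftest import random_network


def triangle_network(w01, w02, w12):
    mat = np.zeros((3, 3))
    mat[0, 1] = mat[1, 0] = w01
    mat[0, 2] = mat[2, 0] = w02
    mat[1, 2] = mat[2, 1] = w12
    return sn.SymptomNetwork(nodes=("a", "b", "c"), matrix=mat, sample_size=5)


class TestWithinBetween:
    def test_three_node_mean(self):
        net = triangle_network(0.2, 0.4, 0.6)
        part = Partition({"a": 0, "b": 0, "c": 0}, "fixed")
        assert sn.within_connectivity(net, part, 0) == pytest.approx(0.4)

    def test_uniform_network_mean_is_weight(self, rng):
        net = random_network(rng)
        net.matrix[:] = 0.3
        np.fill_diagonal(net.matrix, 0)
        part = sn.fixed_hads_partition()
        assert sn.within_connectivity(net, part, 0) == pytest.approx(0.3)
        assert sn.between_connectivity(net, part) == pytest.approx(0.3)

    def test_singleton_community_rejected(self):
        net = triangle_network(0.1, 0.2, 0.3)
        part = Partition({"a": 0, "b": 1, "c": 1}, "fixed")
        with pytest.raises(UndefinedResultError):
            sn.within_connectivity(net, part, 0)

    def test_single_community_between_rejected(self, rng):
        net = random_network(rng)
        part = Partition({n: 0 for n in net.nodes}, "fixed")
        with pytest.raises(UndefinedResultError):
            sn.between_connectivity(net, part)

    def test_matches_brute_force_enumeration(self, rng):
        net = random_network(rng)
        part = sn.fixed_hads_partition()
        pairs = list(itertools.combinations(net.nodes, 2))
        for c in (0, 1):
            manual = np.mean(
                [
                    net.weight(i, j)
                    for i, j in pairs
                    if part.assignment[i] == c and part.assignment[j] == c
                ]
            )
            assert sn.within_connectivity(net, part, c) == pytest.approx(manual)
        cross = [
            net.weight(i, j)
            for i, j in pairs
            if part.assignment[i] != part.assignment[j]
        ]
        assert len(cross) == 49
        assert sn.between_connectivity(net, part) == pytest.approx(np.mean(cross))

    def test_pair_conservation(self, rng):
        """Within and between pair counts exactly partition the 91 edges."""
        net = random_network(rng)
        for labels in ([0] * 7 + [1] * 7, [0, 1, 2] * 4 + [0, 1]):
            part = Partition(dict(zip(net.nodes, labels)), "fixed")
            summary = sn.connectivity_summary(net, part)
            assert sum(summary.within_pairs.values()) + summary.between_pairs == 91


class TestGroupPermutation:
    def test_identical_tables_give_p_one(self, random_table):
        part = sn.fixed_hads_partition()
        res = sn.permutation_test_groups(
            random_table, random_table.copy(), kind="within",
            partition_a=part, partition_b=part, community_a=0, community_b=0,
            n_iter=99, seed=1,
        )
        assert res.observed_diff == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_determinism_and_p_bounds(self, random_table):
        part = sn.fixed_hads_partition()
        kwargs = dict(
            kind="between", partition_a=part, partition_b=part,
            n_iter=150, seed=9,
        )
        a = sn.permutation_test_groups(
            random_table.iloc[:60], random_table.iloc[60:], **kwargs
        )
        b = sn.permutation_test_groups(
            random_table.iloc[:60], random_table.iloc[60:], **kwargs
        )
        assert np.array_equal(a.null_diffs, b.null_diffs)
        assert len(a.null_diffs) == 150
        assert 1 / 151 <= a.p_value <= 1.0

    def test_power_under_coupling_difference(self):
        """Strongly coupled vs uncoupled factors: the between-community
        statistic rejects decisively."""

        def cfg(rho, seed):
            return sn.SyntheticConfig(
                n_participants=800,
                loadings={i: 0.7 for i in sn.ITEM_IDS},
                thresholds={i: (-0.43, 0.43, 1.28) for i in sn.ITEM_IDS},
                factor_correlation=rho,
                group_label=f"g{seed}",
                age_range=(18, 45),
                seed=seed,
            )

        a = sn.generate_cohort(cfg(0.6, 21))
        b = sn.generate_cohort(cfg(0.0, 22))
        part = sn.fixed_hads_partition()
        res = sn.permutation_test_groups(
            a, b, kind="between", partition_a=part, partition_b=part,
            n_iter=500, seed=5,
        )
        assert res.observed_diff > 0
        assert res.p_value <= 0.01

    def test_invalid_n_iter_rejected(self, random_table):
        part = sn.fixed_hads_partition()
        with pytest.raises(ConfigurationError):
            sn.permutation_test_groups(
                random_table, random_table, kind="between",
                partition_a=part, partition_b=part, n_iter=0, seed=0,
            )

    def test_redetect_policy_runs(self, random_table):
        part = sn.fixed_hads_partition()
        res = sn.permutation_test_groups(
            random_table.iloc[:60], random_table.iloc[60:], kind="between",
            partition_a=part, partition_b=part, n_iter=5, seed=3,
            partition_policy="redetect", redetect_restarts=3,
        )
        assert len(res.null_diffs) == 5


class TestCommunityPermutation:
    def test_equal_weights_give_zero_diff_p_one(self, rng):
        net = random_network(rng)
        net.matrix[:] = 0.25
        np.fill_diagonal(net.matrix, 0)
        part = sn.fixed_hads_partition()
        res = sn.permutation_test_communities(net, part, 0, 1, n_iter=99, seed=2)
        assert res.observed_diff == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_planted_blocks_attain_p_floor(self):
        mat = np.full((14, 14), 0.1)
        labels = sn.fixed_hads_partition().labels_for(sn.ITEM_IDS)
        for a in range(14):
            for b in range(14):
                if labels[a] == labels[b] == 0:
                    mat[a, b] = 0.8
        np.fill_diagonal(mat, 0)
        net = sn.SymptomNetwork(nodes=sn.ITEM_IDS, matrix=mat, sample_size=50)
        n_iter = 400
        res = sn.permutation_test_communities(
            net, sn.fixed_hads_partition(), 0, 1, n_iter=n_iter, seed=7
        )
        # only a label permutation that recreates the planted split (chance
        # 2/C(14,7) per draw) can match the observed separation, so p sits
        # at or within a few counts of the attainable floor
        hits = int((abs(res.null_diffs) >= abs(res.observed_diff)).sum())
        assert res.p_value == pytest.approx((1 + hits) / (n_iter + 1))
        assert res.p_value <= 5 / (n_iter + 1)

    def test_null_distribution_centered(self, rng):
        net = random_network(rng)
        res = sn.permutation_test_communities(
            net, sn.fixed_hads_partition(), 0, 1, n_iter=2000, seed=11
        )
        se = res.null_diffs.std(ddof=1) / np.sqrt(len(res.null_diffs))
        assert abs(res.null_diffs.mean()) < 3 * se

    def test_accepts_table_source(self, random_table):
        res = sn.permutation_test_communities(
            random_table, sn.fixed_hads_partition(), 0, 1, n_iter=50, seed=1
        )
        assert len(res.null_diffs) == 50
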