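"""MI estimation and network assembly against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

import symptomnet as sn
from symptomnet.network import nmi_from_pair_codes, pair_codes

from .conftest import naive_entropy_bits, naive_mi_bits, naive_nmi

ordinal_vectors = st.lists(st.integers(0, 3), min_size=2, max_size=60)


class TestJointCounts:
    def test_hand_count(self):
        counts = sn.joint_counts([0, 0, 1], [1, 1, 0])
        assert counts[0, 1] == 2 and counts[1, 0] == 1
        assert counts.sum() == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sn.joint_counts([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sn.joint_counts([0, 1], [0])

    def test_identity_diagonal(self):
        counts = sn.joint_counts([0, 1, 2, 3], [0, 1, 2, 3])
        assert (np.diag(counts) == 1).all() and counts.sum() == 4


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 5), 1.0), ((10, 0, 0, 0), 0.0), ((3, 1), 0.8112781244591328)],
    )
    def test_closed_form_values(self, counts, expected):
        assert sn.entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sn.entropy([0, 0])


class TestMutualInformation:
    def test_self_information_identity(self):
        x = [0, 1, 1, 2, 3, 3, 3]
        hx = naive_entropy_bits(x)
        assert sn.mutual_information(x, x) == pytest.approx(hx, abs=1e-12)

    def test_constant_margin_gives_zero(self):
        assert sn.mutual_information([1] * 6, [0, 1, 2, 0, 1, 2]) == pytest.approx(0.0)

    def test_known_contingency_value(self):
        # joint counts ((2,1),(1,2)) over n=6
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        expected = naive_mi_bits(x, y)
        assert expected == pytest.approx(0.08170416594551044, abs=1e-12)
        assert sn.mutual_information(x, y) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_matches_naive_and_sklearn(self, data):
        x = data.draw(ordinal_vectors)
        y = data.draw(st.lists(st.integers(0, 3), min_size=len(x), max_size=len(x)))
        ours = sn.mutual_information(x, y)
        assert ours == pytest.approx(naive_mi_bits(x, y), abs=1e-10)
        assert ours == pytest.approx(
            mutual_info_score(x, y) / math.log(2), abs=1e-10
        )
        # symmetry and non-negativity
        assert sn.mutual_information(y, x) == pytest.approx(ours, abs=1e-12)
        assert ours >= -1e-12


class TestNormalizedMI:
    def test_perfect_dependence(self):
        assert sn.normalized_mi([0, 1, 2, 0], [0, 1, 2, 0]) == 1.0

    def test_constant_vector_convention(self):
        assert sn.normalized_mi([2] * 5, [0, 1, 0, 1, 0]) == 0.0

    def test_alternative_normalizations_ordered(self, rng):
        # H(X,Y) >= sqrt(HxHy) >= min(Hx,Hy), so the NMI variants nest
        x, y = rng.integers(0, 4, 100), rng.integers(0, 3, 100)
        joint = sn.normalized_mi(x, y, norm="joint")
        geom = sn.normalized_mi(x, y, norm="geometric")
        mn = sn.normalized_mi(x, y, norm="min")
        assert 0 <= joint <= geom <= mn <= 1

    def test_bijective_recoding_invariance(self, rng):
        x = rng.integers(0, 4, 80)
        y = rng.integers(0, 4, 80)
        recode = np.array([2, 0, 3, 1])
        assert sn.normalized_mi(recode[x], y) == pytest.approx(
            sn.normalized_mi(x, y), abs=1e-12
        )


class TestBuildNetwork:
    def test_matches_naive_oracle_elementwise(self, rng):
        for _ in range(5):
            n = int(rng.integers(20, 200))
            X = rng.integers(0, 4, size=(n, 14))
            table = {item: X[:, k] for k, item in enumerate(sn.ITEM_IDS)}
            import pandas as pd

            net = sn.build_network(pd.DataFrame(table))
            for a in range(14):
                for b in range(a + 1, 14):
                    expected = naive_nmi(X[:, a].tolist(), X[:, b].tolist())
                    assert net.matrix[a, b] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_range_and_completeness(self, random_table):
        net = sn.build_network(random_table)
        assert np.allclose(net.matrix, net.matrix.T)
        assert (net.matrix >= 0).all() and (net.matrix <= 1).all()
        assert len(net.edge_list()) == 91
        assert net.sample_size == len(random_table)

    def test_duplicated_column_gives_unit_edge(self, random_table):
        random_table["HA2"] = random_table["HA1"]
        net = sn.build_network(random_table)
        assert net.weight("HA1", "HA2") == 1.0

    def test_constant_item_gives_zero_edges(self, random_table):
        random_table["HD5"] = 2
        net = sn.build_network(random_table)
        for other in sn.ITEM_IDS:
            if other != "HD5":
                assert net.weight("HD5", other) == 0.0

    def test_too_few_rows_rejected(self, random_table):
        with pytest.raises(ValueError):
            sn.build_network(random_table.iloc[:1])

    def test_pair_codes_path_equals_scalar_path(self, rng):
        X = rng.integers(0, 4, size=(60, 5))
        weights = nmi_from_pair_codes(pair_codes(X))
        k = 0
        for a in range(5):
            for b in range(a + 1, 5):
                assert weights[k] == pytest.approx(
                    sn.normalized_mi(X[:, a], X[:, b]), abs=1e-12
                )
                k += 1


class TestNetworkIO:
    def test_edgelist_round_trip(self, tmp_path, random_table):
        net = sn.build_network(random_table)
        path = tmp_path / "edges.csv"
        net.write_edgelist(path)
        back = sn.SymptomNetwork.read_edgelist(path, sample_size=net.sample_size)
        assert back.nodes == net.nodes
        assert np.allclose(back.matrix, net.matrix)

    def test_graphml_has_subscale_and_community(self, tmp_path, random_table):
        import networkx as nx

        net = sn.build_network(random_table)
        part = sn.fixed_hads_partition()
        path = tmp_path / "net.graphml"
        net.write_graphml(path, partition=part.assignment)
        g = nx.read_graphml(path)
        assert g.nodes["HA1"]["subscale"] == "anxiety"
        assert g.nodes["HD3"]["community"] == 1
        assert g.number_of_edges() == 91
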