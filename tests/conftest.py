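import math

import numpy as np
import pandas as pd
import pytest

from symptomnet import ITEM_IDS, SymptomNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_table(rng):
    """Small random cohort table over the 14 items (no latent structure)."""
    n = 120
    data = {item: rng.integers(0, 4, size=n) for item in ITEM_IDS}
    table = pd.DataFrame(data)
    table.insert(0, "group", "toy")
    table.insert(0, "sex", rng.choice(["F", "M"], size=n))
    table.insert(0, "age", rng.integers(18, 90, size=n))
    table.insert(0, "participant_id", [f"T{k:03d}" for k in range(n)])
    return table


def random_network(rng, nodes=ITEM_IDS):
    """Random fully connected symptom network with weights in [0, 1]."""
    p = len(nodes)
    mat = rng.uniform(0, 1, size=(p, p))
    mat = (mat + mat.T) / 2
    np.fill_diagonal(mat, 0.0)
    return SymptomNetwork(nodes=tuple(nodes), matrix=mat, sample_size=100)


# --- independent naive estimators used as oracles --------------------------


def naive_entropy_bits(values):
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    n = len(values)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def naive_mi_bits(x, y):
    n = len(x)
    joint = {}
    for a, b in zip(x, y):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    px = {}
    py = {}
    for a in x:
        px[a] = px.get(a, 0) + 1
    for b in y:
        py[b] = py.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log2(p_ab / ((px[a] / n) * (py[b] / n)))
    return mi


def naive_nmi(x, y):
    hx, hy = naive_entropy_bits(x), naive_entropy_bits(y)
    if hx == 0 or hy == 0:
        return 0.0
    return min(max(naive_mi_bits(x, y) / math.sqrt(hx * hy), 0.0), 1.0)
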