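"""Synthetic ordinal HADS-like cohorts with a known two-factor latent structure.

The generator draws, per participant, a bivariate standard-normal latent pair
(anxiety factor, depression factor) with correlation ``rho`` (the inter-factor
correlation), forms each item's latent response

    y_j = lambda_j * f(j) + sqrt(1 - lambda_j^2) * eps_j,   eps_j ~ N(0, 1),

and discretizes y_j into the ordinal categories 0-3 by three ascending
thresholds. Because y_j is marginally standard normal regardless of the
loading, each item's marginal category distribution is controlled purely by
its thresholds, which lets marginal severities be calibrated to target
per-item means/SDs independently of the dependence structure.

Default configurations for a "young" and an "old" cohort mimic a
community-based ageing cohort in which anxiety severity is higher in the
young group, the anxiety domain is more tightly coupled in the old group,
the depression domain more tightly coupled in the young group, and the two
domains are more strongly inter-correlated in the young group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .errors import ConfigurationError
from .items import ANXIETY, ITEM_IDS, subscale_of

__all__ = [
    "SyntheticConfig",
    "thresholds_from_moments",
    "young_default_config",
    "old_default_config",
    "generate_cohort",
    "generate_two_group_study",
    "load_config",
]

# Default per-item marginal targets (mean, SD on the 0-3 scale) used by the
# young/old default configurations; keyed by item id.
YOUNG_ITEM_MOMENTS: dict[str, tuple[float, float]] = {
    "HA1": (1.06, 0.65), "HA2": (0.69, 0.81), "HA3": (0.98, 0.87),
    "HA4": (0.84, 0.68), "HA5": (0.61, 0.64), "HA6": (1.21, 0.90),
    "HA7": (0.54, 0.67),
    "HD1": (0.46, 0.67), "HD2": (0.26, 0.50), "HD3": (0.35, 0.54),
    "HD4": (0.70, 0.72), "HD5": (0.50, 0.74), "HD6": (0.37, 0.65),
    "HD7": (0.28, 0.63),
}
OLD_ITEM_MOMENTS: dict[str, tuple[float, float]] = {
    "HA1": (0.78, 0.62), "HA2": (0.53, 0.74), "HA3": (0.76, 0.80),
    "HA4": (0.60, 0.63), "HA5": (0.43, 0.59), "HA6": (0.92, 0.82),
    "HA7": (0.49, 0.65),
    "HD1": (0.61, 0.78), "HD2": (0.27, 0.54), "HD3": (0.27, 0.52),
    "HD4": (1.36, 0.93), "HD5": (0.47, 0.71), "HD6": (0.53, 0.72),
    "HD7": (0.19, 0.52),
}

# Item-specific loading offsets added to the subscale base loading in the
# default configurations. Shared by both cohorts, they encode stable
# item-reliability heterogeneity (panic and worry load strongly on the
# anxiety factor; appearance/slowing items are noisier depression markers),
# which keeps centrality profiles correlated across age groups.
ITEM_LOADING_OFFSETS: dict[str, float] = {
    "HA1": 0.04, "HA2": 0.02, "HA3": 0.06, "HA4": -0.04, "HA5": -0.02,
    "HA6": 0.00, "HA7": 0.08,
    "HD1": 0.02, "HD2": 0.05, "HD3": 0.03, "HD4": -0.05, "HD5": -0.08,
    "HD6": 0.00, "HD7": -0.02,
}

_PROB_FLOOR = 1e-6


def thresholds_from_moments(mean: float, sd: float) -> tuple[float, float, float]:
    """Latent thresholds whose discretized standard normal matches (mean, sd).

    Treats the observed 0-3 item as a normal variable N(mean, sd^2) cut at
    0.5, 1.5 and 2.5, takes the implied cumulative category probabilities and
    maps them back onto the standard-normal latent scale. The resulting
    marginal mean matches the target closely for the mildly skewed severity
    distributions typical of community samples.
    """
    if sd <= 0:
        raise ConfigurationError("sd must be positive")
    cum = norm.cdf((np.array([0.5, 1.5, 2.5]) - mean) / sd)
    cum = np.clip(cum, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    t = norm.ppf(cum)
    return (float(t[0]), float(t[1]), float(t[2]))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    ``loadings`` and ``thresholds`` are keyed by item id; every item in the
    14-item catalog must be present. ``factor_correlation`` is the latent
    correlation between the anxiety and depression factors.
    """

    n_participants: int
    loadings: dict[str, float]
    thresholds: dict[str, tuple[float, float, float]]
    factor_correlation: float
    group_label: str
    age_range: tuple[int, int]
    seed: int
    items: tuple[str, ...] = field(default=ITEM_IDS)
    #: when set, rejection-sample so every generated participant satisfies
    #: the subclinical inclusion rule (depression total >= this threshold);
    #: emulates a cohort defined *after* inclusion screening
    condition_min_hads_d: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not -1.0 <= self.factor_correlation <= 1.0:
            raise ConfigurationError("factor_correlation must lie in [-1, 1]")
        missing = [i for i in self.items if i not in self.loadings]
        if missing:
            raise ConfigurationError(f"missing loadings for items: {missing}")
        for item in self.items:
            lam = self.loadings[item]
            if not 0.0 <= lam <= 1.0:
                raise ConfigurationError(f"loading for {item} outside [0, 1]: {lam}")
            thr = self.thresholds.get(item)
            if thr is None or len(thr) != 3:
                raise ConfigurationError(f"item {item} needs exactly 3 thresholds")
            if not (thr[0] < thr[1] < thr[2]):
                raise ConfigurationError(
                    f"thresholds for {item} must be strictly ascending, got {thr}"
                )
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 18:
            raise ConfigurationError("age_range must satisfy 18 <= min <= max")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _uniform_config(
    moments: dict[str, tuple[float, float]],
    anx_loading: float,
    dep_loading: float,
    rho: float,
    n: int,
    label: str,
    age_range: tuple[int, int],
    seed: int,
    condition_min_hads_d: int | None = None,
) -> SyntheticConfig:
    loadings = {
        i: (anx_loading if subscale_of(i) == ANXIETY else dep_loading)
        + ITEM_LOADING_OFFSETS[i]
        for i in ITEM_IDS
    }
    thresholds = {i: thresholds_from_moments(*moments[i]) for i in ITEM_IDS}
    return SyntheticConfig(
        n_participants=n,
        loadings=loadings,
        thresholds=thresholds,
        factor_correlation=rho,
        group_label=label,
        age_range=age_range,
        seed=seed,
        condition_min_hads_d=condition_min_hads_d,
    )


def young_default_config(n: int = 232, seed: int = 0) -> SyntheticConfig:
    """Default young-adult included cohort: ages 18-45, depression total >= 4.

    Loadings and inter-factor correlation are chosen so the included sample
    shows acceptable internal consistency on both subscales and a stronger
    anxiety-depression coupling than the older cohort.
    """
    return _uniform_config(
        YOUNG_ITEM_MOMENTS, anx_loading=0.70, dep_loading=0.84, rho=0.50,
        n=n, label="young", age_range=(18, 45), seed=seed,
        condition_min_hads_d=4,
    )


def old_default_config(n: int = 554, seed: int = 1) -> SyntheticConfig:
    """Default older-adult included cohort: ages 65-88, depression total >= 4.

    Relative to the young defaults: a tighter anxiety domain, a looser
    depression domain, and weaker anxiety-depression coupling.
    """
    return _uniform_config(
        OLD_ITEM_MOMENTS, anx_loading=0.80, dep_loading=0.72, rho=0.30,
        n=n, label="old", age_range=(65, 88), seed=seed,
        condition_min_hads_d=4,
    )


def generate_cohort(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate one cohort as a participant x item table.

    Returns a DataFrame with columns ``participant_id, age, sex, group`` and
    one column per item, values in {0, 1, 2, 3}. Identical config (including
    seed) yields a bit-identical table.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_participants
    rho = config.factor_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])

    def draw_items(m: int) -> dict[str, np.ndarray]:
        factors = rng.multivariate_normal(np.zeros(2), cov, size=m, method="cholesky")
        anx_f, dep_f = factors[:, 0], factors[:, 1]
        out: dict[str, np.ndarray] = {}
        for item in config.items:
            lam = config.loadings[item]
            f = anx_f if subscale_of(item) == ANXIETY else dep_f
            y = lam * f + np.sqrt(1.0 - lam * lam) * rng.standard_normal(m)
            out[item] = np.digitize(y, config.thresholds[item]).astype(np.int64)
        return out

    if config.condition_min_hads_d is None:
        data = draw_items(n)
    else:
        dep_items = [i for i in config.items if subscale_of(i) != ANXIETY]
        kept: list[dict[str, np.ndarray]] = []
        n_kept = 0
        while n_kept < n:
            batch = draw_items(max(n, 64))
            total = sum(batch[i] for i in dep_items)
            keep = total >= config.condition_min_hads_d
            kept.append({k: v[keep] for k, v in batch.items()})
            n_kept += int(keep.sum())
        data = {
            k: np.concatenate([chunk[k] for chunk in kept])[:n]
            for k in config.items
        }

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    sex = rng.choice(np.array(["F", "M"]), size=n)
    table = pd.DataFrame(
        {
            "participant_id": [f"{config.group_label}-{k:05d}" for k in range(n)],
            "age": ages,
            "sex": sex,
            "group": config.group_label,
        }
    )
    for item in config.items:
        table[item] = data[item]
    return table


def generate_two_group_study(
    young_cfg: SyntheticConfig, old_cfg: SyntheticConfig
) -> pd.DataFrame:
    """Concatenate two independently generated cohorts into one study table."""
    if young_cfg.group_label == old_cfg.group_label:
        raise ConfigurationError(
            f"group labels must differ, both are {young_cfg.group_label!r}"
        )
    a = generate_cohort(young_cfg)
    b = generate_cohort(old_cfg)
    return pd.concat([a, b], ignore_index=True)


def load_config(path: str) -> SyntheticConfig:
    """Read a cohort configuration from a YAML file.

    Expected keys: ``n_participants, factor_correlation, group_label,
    age_range ([min, max]), seed`` and either scalar ``anxiety_loading`` /
    ``depression_loading`` plus per-item ``marginal_means``/``marginal_sds``
    mappings, or explicit per-item ``loadings`` and ``thresholds`` mappings.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "loadings" in raw:
        loadings = {k: float(v) for k, v in raw["loadings"].items()}
    else:
        loadings = {
            i: float(
                raw["anxiety_loading"]
                if subscale_of(i) == ANXIETY
                else raw["depression_loading"]
            )
            for i in ITEM_IDS
        }
    if "thresholds" in raw:
        thresholds = {k: tuple(float(x) for x in v) for k, v in raw["thresholds"].items()}
    else:
        thresholds = {
            i: thresholds_from_moments(
                float(raw["marginal_means"][i]), float(raw["marginal_sds"][i])
            )
            for i in ITEM_IDS
        }
    return SyntheticConfig(
        n_participants=int(raw["n_participants"]),
        loadings=loadings,
        thresholds=thresholds,
        factor_correlation=float(raw["factor_correlation"]),
        group_label=str(raw["group_label"]),
        age_range=(int(raw["age_range"][0]), int(raw["age_range"][1])),
        seed=int(raw["seed"]),
        condition_min_hads_d=(
            int(raw["condition_min_hads_d"])
            if raw.get("condition_min_hads_d") is not None
            else None
        ),
    )
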