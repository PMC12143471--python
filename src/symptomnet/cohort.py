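"""Cohort table I/O, HADS scoring, inclusion filtering and age grouping.

A cohort is a pandas DataFrame with one row per participant and columns
``participant_id, age, sex, group, HA1..HA7, HD1..HD7``. Items are assumed
already severity-coded 0-3 (no reverse-scoring is applied here). Rows with
missing or out-of-range item values are excluded before analysis, mirroring
a complete-cases design.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import CohortFormatError, ConfigurationError
from .items import ANXIETY_ITEMS, DEPRESSION_ITEMS, ITEM_IDS

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("age",) + ITEM_IDS
COHORT_COLUMNS = ("participant_id", "age", "sex", "group") + ITEM_IDS

YOUNG_MAX_AGE = 45   # young adults: 18-45 inclusive
MIDDLE_MAX_AGE = 64  # middle-aged: 46-64; older adults: 65+
DEFAULT_MIN_HADS_D = 4  # at least subclinical depressive symptoms


def write_cohort(table: pd.DataFrame, path: str) -> None:
    """Write a cohort table to CSV in the canonical column order."""
    cols = [c for c in COHORT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)


def read_cohort(path: str) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`CohortFormatError` if a required column is absent or an
    item value cannot be parsed as a number. Rows with missing or
    out-of-range item values (outside {0,1,2,3}) are dropped with a logged
    count.
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CohortFormatError(f"cohort file {path} missing column(s): {missing}")

    for col in ITEM_IDS:
        raw = table[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise CohortFormatError(
                f"unparseable value {raw[row]!r} in column {col}, row {row}"
            )
        table[col] = parsed

    items = table[list(ITEM_IDS)]
    ok = items.notna().all(axis=1) & items.isin([0, 1, 2, 3]).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "dropping %d row(s) with missing or out-of-range item values", n_dropped
        )
    table = table.loc[ok].copy()
    table[list(ITEM_IDS)] = table[list(ITEM_IDS)].astype(int)
    if "participant_id" not in table.columns:
        table.insert(0, "participant_id", [f"P{k:05d}" for k in range(len(table))])
    return table.reset_index(drop=True)


def score_hads(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant HADS subscale totals.

    Returns a DataFrame (aligned with ``table``'s index) with columns
    ``hads_a_total`` and ``hads_d_total``, each the sum of the seven items of
    the subscale, hence in [0, 21].
    """
    return pd.DataFrame(
        {
            "hads_a_total": table[list(ANXIETY_ITEMS)].sum(axis=1),
            "hads_d_total": table[list(DEPRESSION_ITEMS)].sum(axis=1),
        },
        index=table.index,
    )


def filter_subclinical(
    table: pd.DataFrame, min_hads_d: int = DEFAULT_MIN_HADS_D
) -> pd.DataFrame:
    """Keep participants with at least subclinical depressive symptoms.

    Retains rows whose HADS-D total is >= ``min_hads_d`` (boundary
    inclusive). The default of 4 marks at least mild depressive
    symptomatology.
    """
    if min_hads_d < 0:
        raise ConfigurationError("min_hads_d must be non-negative")
    scores = score_hads(table)
    keep = scores["hads_d_total"] >= min_hads_d
    logger.info(
        "inclusion filter HADS-D >= %d: retained %d of %d participants",
        min_hads_d, int(keep.sum()), len(table),
    )
    return table.loc[keep].reset_index(drop=True)


def assign_age_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Label participants young (18-45), middle (46-64) or old (65+).

    Rows with age below 18 are excluded with a warning. Any pre-existing
    ``group`` column is overwritten.
    """
    adult = table["age"] >= 18
    if (~adult).any():
        logger.warning("excluding %d row(s) with age < 18", int((~adult).sum()))
    table = table.loc[adult].reset_index(drop=True)
    group = pd.Series("old", index=table.index, dtype=object)
    group[table["age"] <= MIDDLE_MAX_AGE] = "middle"
    group[table["age"] <= YOUNG_MAX_AGE] = "young"
    out = table.copy()
    out["group"] = group
    return out
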