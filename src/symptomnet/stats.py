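"""Descriptive group-comparison statistics for cohort tables.

Welch two-sample t-tests (unequal variances, Welch-Satterthwaite df),
Mann-Whitney U with midranks and the normal approximation, Pearson 2x2
chi-square, Cronbach's alpha, and Benjamini-Hochberg FDR adjustment. All
sample variances use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedResultError
from .items import ITEM_IDS, ITEM_LABELS

__all__ = [
    "welch_t",
    "welch_t_from_samples",
    "mann_whitney_u",
    "chi_square_2x2",
    "cronbach_alpha",
    "bh_fdr",
    "compare_item_severity",
    "group_characteristics",
]


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t-test from group summaries; returns (t, df, two-sided p).

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with Welch-Satterthwaite
    degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0:
        raise UndefinedResultError("zero variance in both groups: t undefined")
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_from_samples(x, y) -> tuple[float, float, float]:
    """Welch t-test on raw vectors; returns (t, df, two-sided p)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    return welch_t(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def mann_whitney_u(x, y, continuity: bool = True) -> tuple[float, float]:
    """Mann-Whitney U with midranks; returns (U, two-sided p).

    U counts pairs (x_i, y_j) with x_i > y_j plus half the ties (the
    "wins + half-ties for x" convention): x entirely below y gives U = 0,
    x entirely above gives U = n1*n2. The p-value uses the tie-corrected
    normal approximation (continuity-corrected by default).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic",
        use_continuity=continuity,
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table [[a, b], [c, d]], 1 df.

    No continuity correction by default; pass ``correction=True`` for Yates.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a participant-by-item score matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total)), sample
    variances with denominator n-1.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 participants and >= 2 items")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedResultError("zero total-score variance: alpha undefined")
    return float(k / (k - 1) * (1 - X.var(axis=0, ddof=1).sum() / total_var))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_item_severity(
    table: pd.DataFrame, group_col: str = "group"
) -> pd.DataFrame:
    """Per-item two-sample comparison between the two groups of a cohort.

    For each of the 14 items, reports per-group mean and SD, the
    Mann-Whitney U (with its p) and the Welch t (with df and p), plus
    BH-FDR-adjusted p-values computed within each test family across the 14
    items. The two families are emitted side by side because either may be
    preferred for 4-level ordinal scores.
    """
    groups = [g for g in table[group_col].unique()]
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g1, g2 = groups
    t1, t2 = table[table[group_col] == g1], table[table[group_col] == g2]
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be non-empty")

    rows = []
    for item in ITEM_IDS:
        x, y = t1[item].to_numpy(float), t2[item].to_numpy(float)
        u, p_u = mann_whitney_u(x, y)
        t, df, p_t = welch_t_from_samples(x, y)
        rows.append(
            {
                "item": item,
                "label": ITEM_LABELS[item],
                f"mean_{g1}": x.mean(), f"sd_{g1}": x.std(ddof=1),
                f"mean_{g2}": y.mean(), f"sd_{g2}": y.std(ddof=1),
                "u_stat": u, "p_u": p_u,
                "t_stat": t, "df_t": df, "p_t": p_t,
            }
        )
    out = pd.DataFrame(rows)
    out["p_u_fdr"] = bh_fdr(out["p_u"].clip(lower=np.nextafter(0, 1)))
    out["p_t_fdr"] = bh_fdr(out["p_t"].clip(lower=np.nextafter(0, 1)))
    return out


def group_characteristics(
    table: pd.DataFrame,
    hads_scores: pd.DataFrame,
    group_col: str = "group",
) -> pd.DataFrame:
    """Cohort-characteristics comparison (age, sex, subscale totals).

    ``hads_scores`` is the output of :func:`symptomnet.cohort.score_hads`
    aligned with ``table``. Continuous rows use Welch t; the sex row uses
    the 2x2 Pearson chi-square.
    """
    groups = [g for g in table[group_col].unique()]
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g1, g2 = groups
    m1, m2 = table[group_col] == g1, table[group_col] == g2

    rows = []

    def cont_row(name, v1, v2, test=True):
        row = {
            "variable": name,
            f"mean_{g1}": v1.mean(), f"sd_{g1}": v1.std(ddof=1),
            f"mean_{g2}": v2.mean(), f"sd_{g2}": v2.std(ddof=1),
        }
        if test:
            t, df, p = welch_t_from_samples(v1, v2)
            row.update(statistic="welch_t", value=t, df=df, p=p)
        rows.append(row)

    cont_row("age", table.loc[m1, "age"], table.loc[m2, "age"], test=False)
    cont_row("hads_d_total", hads_scores.loc[m1.values, "hads_d_total"],
             hads_scores.loc[m2.values, "hads_d_total"])
    cont_row("hads_a_total", hads_scores.loc[m1.values, "hads_a_total"],
             hads_scores.loc[m2.values, "hads_a_total"])

    if "sex" in table.columns and table["sex"].nunique() == 2:
        levels = sorted(table["sex"].unique())
        a = int(((table[group_col] == g1) & (table["sex"] == levels[0])).sum())
        b = int(((table[group_col] == g1) & (table["sex"] == levels[1])).sum())
        c = int(((table[group_col] == g2) & (table["sex"] == levels[0])).sum())
        d = int(((table[group_col] == g2) & (table["sex"] == levels[1])).sum())
        chi2, p = chi_square_2x2(a, b, c, d)
        rows.append(
            {
                "variable": "sex",
                f"mean_{g1}": a, f"sd_{g1}": a + b,
                f"mean_{g2}": c, f"sd_{g2}": c + d,
                "statistic": "chi2", "value": chi2, "df": 1.0, "p": p,
            }
        )
    return pd.DataFrame(rows)
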