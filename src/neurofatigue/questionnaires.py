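"""Mood (BMIS) and fatigue (ZEF) scoring, reliability, and paired
condition comparisons.

Scoring: BMIS overall = pleasant total - unpleasant total (8/8 polarity
split, so the overall lies in [-24, 24]); ZEF overall = mean of all 18
items, dimension scores = mean of that dimension's three items (the three
items not covered by the five dimensions contribute only to the overall).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import (
    bh_adjust,
    fit_random_intercept,
    significance_stars,
    wilcoxon_paired,
)
from .synth.questionnaire import (
    BMIS_ITEMS,
    BMIS_PLEASANT,
    BMIS_UNPLEASANT,
    ZEF_DIMENSIONS,
    ZEF_ITEMS,
)


def _check_items(table: pd.DataFrame, items, lo: int, hi: int, name: str) -> None:
    missing = [c for c in items if c not in table.columns]
    if missing:
        raise ValueError(f"{name} table is missing items {missing}")
    block = table[list(items)]
    if block.isna().any().any():
        raise ValueError(f"{name} table contains missing responses; no imputation")
    vals = block.to_numpy()
    if ((vals < lo) | (vals > hi)).any():
        raise ValueError(f"{name} responses must lie in [{lo}, {hi}]")


def bmis_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Positive, negative and overall mood score per response row."""
    _check_items(table, BMIS_ITEMS, 1, 4, "BMIS")
    out = table.drop(columns=list(BMIS_ITEMS)).copy()
    out["positive"] = table[list(BMIS_PLEASANT)].sum(axis=1)
    out["negative"] = table[list(BMIS_UNPLEASANT)].sum(axis=1)
    out["overall"] = out["positive"] - out["negative"]
    return out


def zef_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Overall (mean of all 18 items) and per-dimension mean scores."""
    _check_items(table, ZEF_ITEMS, 1, 5, "ZEF")
    out = table.drop(columns=list(ZEF_ITEMS)).copy()
    out["overall"] = table[list(ZEF_ITEMS)].mean(axis=1)
    for dim, items in ZEF_DIMENSIONS.items():
        out[dim] = table[list(items)].mean(axis=1)
    return out


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """k/(k-1) * (1 - sum of item variances / variance of the item sums).

    NaN when the total-score variance is zero.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a subjects x items matrix with >= 2 items")
    if X.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def paired_condition_tests(
    a: pd.DataFrame, b: pd.DataFrame, items, on: str = "subject"
) -> pd.DataFrame:
    """Per-item paired signed-rank tests between two conditions with BH
    correction across items and significance stars.

    ``a``/``b`` hold one row per subject (same subjects, matched on
    ``on``); ``items`` lists the columns to test.
    """
    a = a.sort_values(on).reset_index(drop=True)
    b = b.sort_values(on).reset_index(drop=True)
    if not a[on].equals(b[on]):
        raise ValueError("conditions must cover the same subjects")
    rows = []
    for item in items:
        stat, p = wilcoxon_paired(a[item].to_numpy(), b[item].to_numpy())
        rows.append({"item": item, "statistic": stat, "p": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["stars"] = table["p_adj"].map(significance_stars)
    return table


def order_effect_check(scores: pd.DataFrame, value: str = "overall") -> pd.DataFrame:
    """score ~ order + condition + order:condition + (1 | subject).

    ``scores`` needs columns subject, condition, ``value`` and ``order``
    (the subject's starting condition). Returns the fixed-effect table.
    """
    for col in ("subject", "condition", "order", value):
        if col not in scores.columns:
            raise ValueError(f"scores table needs a {col!r} column")
    cond = (scores["condition"] == "videoconference").astype(float).to_numpy()
    order = (scores["order"] == "videoconference_first").astype(float).to_numpy()
    exog = pd.DataFrame(
        {"order": order, "condition": cond, "order_x_condition": order * cond}
    )
    res = fit_random_intercept(
        scores[value].to_numpy(dtype=float), exog, scores["subject"].to_numpy()
    )
    table = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    table["fallback"] = res.used_fallback
    return table[table["term"] != "const"].reset_index(drop=True)


__all__ = [
    "bmis_scores",
    "zef_scores",
    "cronbach_alpha",
    "paired_condition_tests",
    "order_effect_check",
]
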