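"""Linking physiological indices to questionnaire items, plus window-wise
and averaged paired condition comparisons with BH correction.

BH families are frozen per figure-equivalent panel: window-wise tests are
corrected across windows within one index x channel; item-link models are
corrected across the item x index cells of one model family.
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
from .types import WindowedFeatureSeries


def summarize_index(series: WindowedFeatureSeries) -> float:
    """Unweighted mean over valid (finite) complete windows; NaN if none."""
    mask = series.valid_mask()
    if not mask.any():
        return float("nan")
    return float(series.values[mask].mean())


def fit_index_item_lme(
    summaries: pd.DataFrame,
    items: pd.DataFrame,
    model: str = "item_fatigue",
    include_before: bool = False,
    include_condition: bool = False,
) -> pd.DataFrame:
    """index_average ~ [item_before +] item_after + (1 | subject), pooling
    both conditions, for every index x item pair.

    ``summaries``: columns subject, condition, index, value (one row per
    subject x condition x index). ``items``: columns subject, condition,
    item, score_after [, score_before]; scores must be z-normalized across
    all subjects and conditions. The standardized effect is the
    item_after coefficient over the residual SD; BH runs across the whole
    index x item family.
    """
    rows = []
    for index_name, sub in summaries.groupby("index"):
        for item_name, it in items.groupby("item"):
            merged = sub.merge(it, on=["subject", "condition"], how="inner")
            if merged.empty:
                continue
            exog = {"item_after": merged["score_after"].to_numpy(dtype=float)}
            if include_before:
                exog["item_before"] = merged["score_before"].to_numpy(dtype=float)
            if include_condition:
                exog["condition"] = (
                    merged["condition"] == "videoconference"
                ).to_numpy(dtype=float)
            res = fit_random_intercept(
                merged["value"].to_numpy(dtype=float),
                pd.DataFrame(exog),
                merged["subject"].to_numpy(),
            )
            est = float(res.params["item_after"])
            std = est / res.resid_sd if res.resid_sd > 0 else np.sign(est) * np.inf
            rows.append(
                {
                    "index": index_name,
                    "item": item_name,
                    "estimate": est,
                    "std_effect": std,
                    "p": float(res.pvalues["item_after"]),
                    "model": model,
                    "fallback": res.used_fallback,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table


def windowwise_condition_test(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Paired signed-rank per window between two conditions.

    ``a``/``b`` are (n_subjects, n_windows) matrices on the same window
    grid, rows paired by subject. BH runs across windows (one index x
    channel family). Returns window, p, p_adj, significant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition matrices must share the subject x window grid")
    rows = []
    for w in range(a.shape[1]):
        _, p = wilcoxon_paired(a[:, w], b[:, w])
        rows.append({"window": w, "p": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table


def average_condition_test(
    summaries_a: pd.DataFrame, summaries_b: pd.DataFrame
) -> pd.DataFrame:
    """Paired signed-rank on per-subject time-averaged values, one test per
    index, BH across the index family, star encoding."""
    rows = []
    for index_name, sub_a in summaries_a.groupby("index"):
        sub_b = summaries_b[summaries_b["index"] == index_name]
        merged = sub_a.merge(sub_b, on="subject", suffixes=("_a", "_b"))
        if merged.empty:
            continue
        stat, p = wilcoxon_paired(
            merged["value_a"].to_numpy(), merged["value_b"].to_numpy()
        )
        rows.append({"index": index_name, "statistic": stat, "p": p})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table["stars"] = table["p_adj"].map(significance_stars)
    return table


__all__ = [
    "summarize_index",
    "fit_index_item_lme",
    "windowwise_condition_test",
    "average_condition_test",
]
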