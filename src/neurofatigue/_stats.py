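"""Shared statistical primitives: BH correction, paired signed-rank test,
and the random-intercept mixed model with its OLS fallback."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def wilcoxon_paired(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank on paired samples; exact null for small n,
    normal approximation with continuity correction otherwise.

    All-zero differences give (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have the same shape")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    n_nonzero = int(np.count_nonzero(d))
    method = "exact" if n_nonzero <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True, method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True, method="approx")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# random-intercept LME


@dataclass
class MixedFitResult:
    """Fixed effects of a random-intercept model (or its OLS fallback)."""

    params: pd.Series
    pvalues: pd.Series
    resid_sd: float
    group_var: float
    used_fallback: bool


def fit_random_intercept(
    endog: np.ndarray,
    exog: pd.DataFrame,
    groups: np.ndarray,
    reml: bool = True,
) -> MixedFitResult:
    """Fit ``endog ~ exog + (1 | groups)`` by (RE)ML.

    Falls back to fixed-effects-only OLS when the mixed fit fails to
    converge or is singular; when the estimated random-intercept variance
    is (numerically) zero the fixed effects are refit by OLS so that the
    documented OLS-equivalence holds exactly.
    """
    endog = np.asarray(endog, dtype=float)
    exog = sm.add_constant(pd.DataFrame(exog), has_constant="add")
    for col in exog.columns:
        if col != "const" and np.ptp(exog[col].to_numpy()) == 0:
            raise ValueError(f"predictor {col!r} is constant; effect undefined")

    groups = np.asarray(groups)
    _, counts = np.unique(groups, return_counts=True)
    if counts.max() < 2:
        # a by-group intercept is unidentifiable with one observation per
        # group; the honest model is fixed-effects-only
        ols = sm.OLS(endog, exog).fit()
        return MixedFitResult(
            ols.params, ols.pvalues, float(np.sqrt(ols.scale)), 0.0, True
        )

    used_fallback = False
    group_var = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog, exog, groups=groups)
            fit = model.fit(reml=reml, method=["lbfgs", "bfgs"])
        group_var = float(np.squeeze(fit.cov_re.to_numpy()))
        converged = bool(getattr(fit, "converged", True))
        if not converged or not np.isfinite(fit.params).all():
            used_fallback = True
    except (np.linalg.LinAlgError, ValueError):
        used_fallback = True
        fit = None

    if not used_fallback and group_var > 1e-8:
        params = fit.fe_params
        pvalues = fit.pvalues[params.index]
        resid_sd = float(np.sqrt(fit.scale))
        return MixedFitResult(params, pvalues, resid_sd, group_var, False)

    # boundary (zero random-intercept variance) or failure -> OLS
    ols = sm.OLS(endog, exog).fit()
    resid_sd = float(np.sqrt(ols.scale))
    return MixedFitResult(
        ols.params, ols.pvalues, resid_sd, 0.0 if not used_fallback else np.nan,
        used_fallback,
    )


def zscore_items(table: pd.DataFrame, item_columns) -> pd.DataFrame:
    """Normalize item columns to zero mean / unit SD across all rows
    (i.e., across subjects and conditions together)."""
    out = table.copy()
    for col in item_columns:
        v = out[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"item {col!r} is constant; cannot standardize")
        out[col] = (v - v.mean()) / sd
    return out


__all__ = [
    "bh_adjust",
    "significance_stars",
    "wilcoxon_paired",
    "MixedFitResult",
    "fit_random_intercept",
    "zscore_items",
]
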