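"""Descriptive prevalence summaries and simple association tests.

Plaque prevalence tables with Wilson confidence intervals, the pooled
two-proportion z-test, the Cochran-Armitage trend test over ordered
categories, the Wilcoxon rank-sum (Mann-Whitney) test, and multivariable
logistic regression (delegated to statsmodels) with odds ratios reported per
SD for continuous covariates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

#: Age bands used for prevalence-by-age summaries; "<45" kept separate.
DEFAULT_AGE_BANDS = ((-np.inf, 45), (45, 55), (55, 65), (65, 75), (75, np.inf))
AGE_BAND_LABELS = ("<45", "45-54", "55-64", "65-74", ">=75")


def age_band(age) -> np.ndarray:
    """Map ages to band labels."""
    age = np.asarray(age, dtype=float)
    out = np.empty(age.shape, dtype=object)
    for (lo, hi), label in zip(DEFAULT_AGE_BANDS, AGE_BAND_LABELS):
        out[(age >= lo) & (age < hi)] = label
    return out


def prevalence_table(cohort: pd.DataFrame, by=("sex", "age_band"),
                     outcome: str = "plaque_present") -> pd.DataFrame:
    """Prevalence of a binary outcome by group with Wilson 95% CIs.

    Empty groups are reported with missing prevalence and a warning.
    """
    df = cohort.copy()
    if "age_band" in by and "age_band" not in df.columns:
        df["age_band"] = age_band(df["age"])
    rows = []
    for keys, sub in df.groupby(list(by), observed=False, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n = len(sub)
        if n == 0:
            warnings.warn(f"empty group {keys!r}", stacklevel=2)
            rows.append(dict(zip(by, keys), n=0, x=0, prevalence=np.nan,
                             ci_low=np.nan, ci_high=np.nan))
            continue
        x = int(sub[outcome].sum())
        lo, hi = proportion_confint(x, n, method="wilson")
        rows.append(dict(zip(by, keys), n=n, x=x, prevalence=x / n,
                         ci_low=lo, ci_high=hi))
    return pd.DataFrame(rows)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> dict:
    """Pooled-variance two-proportion z-test, two-sided."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    p = (x1 + x2) / (n1 + n2)
    var = p * (1 - p) * (1 / n1 + 1 / n2)
    if var == 0:
        return {"z": 0.0, "p": 1.0}
    z = (p1 - p2) / np.sqrt(var)
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


def cochran_armitage(cases, totals, scores=None) -> dict:
    """Cochran-Armitage trend test over ordered categories (two-sided).

    ``cases[i]`` of ``totals[i]`` are positive in category i; ``scores``
    default to equally spaced 0..k-1.  With two categories the squared
    statistic equals the pooled two-proportion z squared.
    """
    cases = np.asarray(cases, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("category totals must be positive")
    k = len(cases)
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    n = totals.sum()
    pbar = cases.sum() / n
    num = np.sum(s * (cases - totals * pbar))
    var = pbar * (1 - pbar) * (np.sum(totals * s**2) - np.sum(totals * s) ** 2 / n)
    if var == 0:
        return {"z": 0.0, "p": 1.0}
    z = num / np.sqrt(var)
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


def rank_sum_test(x, y) -> dict:
    """Mann-Whitney rank-sum test, normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def fit_logistic(design: pd.DataFrame, outcome, standardize_continuous: bool = True) -> dict:
    """Multivariable logistic regression via maximum likelihood.

    Continuous covariates (more than two distinct values) are standardised
    per SD when ``standardize_continuous`` so that odds ratios read per-SD.
    Perfect separation raises an error.
    """
    X = design.copy().astype(float)
    scaled = []
    if standardize_continuous:
        for col in X.columns:
            if X[col].nunique() > 2:
                X[col] = (X[col] - X[col].mean()) / X[col].std()
                scaled.append(col)
    X = sm.add_constant(X)
    model = sm.Logit(np.asarray(outcome, dtype=float), X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = model.fit(disp=False)
    except Exception as err:
        raise RuntimeError(f"logistic fit failed (separation or non-convergence): {err}") from err
    params = fit.params.drop("const")
    return {
        "log_or": params.to_dict(),
        "se": fit.bse.drop("const").to_dict(),
        "odds_ratio": np.exp(params).to_dict(),
        "scaled_per_sd": scaled,
        "model": fit,
    }
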