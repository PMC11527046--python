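"""Two-sample summary-statistics Mendelian randomization estimators.

Operates on per-variant summary associations (beta and SE for an exposure
and an outcome): inverse-variance weighted (IVW) meta-analysis of Wald
ratios with a multiplicative random-effects option, MR-Egger regression for
directional pleiotropy, the weighted median estimator, Cochran's Q
heterogeneity statistic, and the ln(2) scaling used to express effects of
binary exposures per two-fold increase in prevalence.

Wald-ratio standard errors use the first-order delta method
(se_out / |beta_exp|), the conventional default that ignores exposure-side
uncertainty in the weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LN2 = math.log(2.0)


@dataclass
class InstrumentSet:
    """Per-SNV summary statistics for one exposure-outcome pair."""

    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    ids: list | None = None

    def __post_init__(self):
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        if self.beta_exposure.size == 0:
            raise ValueError("need at least one instrument")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be > 0")

    def __len__(self) -> int:
        return self.beta_exposure.size

    @classmethod
    def from_tsv(cls, path) -> "InstrumentSet":
        df = pd.read_csv(path, sep="\t")
        required = ["snp", "beta_exp", "se_exp", "beta_out", "se_out"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"instrument TSV missing columns: {missing}")
        return cls(df["beta_exp"], df["se_exp"], df["beta_out"], df["se_out"],
                   ids=list(df["snp"]))

    def oriented(self) -> "InstrumentSet":
        """Flip each SNV so the exposure beta is positive (Egger convention)."""
        sign = np.where(self.beta_exposure < 0, -1.0, 1.0)
        return InstrumentSet(self.beta_exposure * sign, self.se_exposure,
                             self.beta_outcome * sign, self.se_outcome, self.ids)


def _ratios(inst: InstrumentSet):
    ratio = inst.beta_outcome / inst.beta_exposure
    se = inst.se_outcome / np.abs(inst.beta_exposure)
    return ratio, se


def ivw(inst: InstrumentSet, random_effects: bool = True) -> dict:
    """Inverse-variance weighted estimate of the causal effect.

    Fixed effects equal the weighted-least-squares slope through the origin.
    The (multiplicative) random-effects model inflates the SE by
    max(1, sqrt(Q / (k - 1))) for k > 1.
    """
    ratio, se = _ratios(inst)
    w = 1.0 / se**2
    beta = float(np.sum(w * ratio) / np.sum(w))
    beta_se = float(np.sqrt(1.0 / np.sum(w)))
    k = len(inst)
    q = float(np.sum(w * (ratio - beta) ** 2))
    if random_effects and k > 1:
        beta_se *= max(1.0, math.sqrt(q / (k - 1)))
    ci = (beta - 1.96 * beta_se, beta + 1.96 * beta_se)
    return {"beta": beta, "se": beta_se, "ci": ci,
            "or": math.exp(beta), "or_ci": tuple(math.exp(c) for c in ci),
            "q": q, "k": k}


def mr_egger(inst: InstrumentSet) -> dict:
    """MR-Egger: weighted regression of outcome betas on exposure betas with
    a free intercept (weights 1/se_out^2), after orienting exposure betas
    positive.  The intercept estimates directional pleiotropy."""
    if len(inst) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    o = inst.oriented()
    w = 1.0 / o.se_outcome**2
    X = np.column_stack([np.ones(len(o)), o.beta_exposure])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    coef = np.linalg.solve(xtwx, X.T @ (w * o.beta_outcome))
    resid = o.beta_outcome - X @ coef
    k = len(o)
    sigma2 = max(1.0, float(np.sum(w * resid**2) / (k - 2)))  # multiplicative overdispersion
    cov = np.linalg.inv(xtwx) * sigma2
    se = np.sqrt(np.diag(cov))
    t_int = coef[0] / se[0]
    t_slope = coef[1] / se[1]
    return {
        "slope": float(coef[1]),
        "slope_se": float(se[1]),
        "slope_p": float(2 * stats.t.sf(abs(t_slope), k - 2)),
        "intercept": float(coef[0]),
        "intercept_se": float(se[0]),
        "intercept_p": float(2 * stats.t.sf(abs(t_int), k - 2)),
    }


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (as used for MR weighted-median)."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return float(np.interp(0.5, cw, v))


def weighted_median(inst: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> dict:
    """Weighted-median estimator: consistent when instruments carrying at
    least half the weight are valid.  SE from a parametric bootstrap of the
    per-SNV summary statistics."""
    ratio, se = _ratios(inst)
    w = 1.0 / se**2
    beta = _weighted_median(ratio, w)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        be = rng.normal(inst.beta_exposure, inst.se_exposure)
        bo = rng.normal(inst.beta_outcome, inst.se_outcome)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = bo / be
        s = inst.se_outcome / np.abs(be)
        ok = np.isfinite(r) & (s > 0)
        reps[b] = _weighted_median(r[ok], 1.0 / s[ok] ** 2)
    se_boot = float(np.std(reps, ddof=1))
    return {"beta": beta, "se": se_boot,
            "ci": (beta - 1.96 * se_boot, beta + 1.96 * se_boot)}


def cochran_q(inst: InstrumentSet, beta: float | None = None) -> dict:
    """Cochran's Q heterogeneity of the Wald ratios around ``beta``
    (defaults to the fixed-effects IVW estimate); df = k - 1."""
    if len(inst) < 2:
        raise ValueError("heterogeneity undefined for a single instrument")
    ratio, se = _ratios(inst)
    w = 1.0 / se**2
    if beta is None:
        beta = float(np.sum(w * ratio) / np.sum(w))
    q = float(np.sum(w * (ratio - beta) ** 2))
    df = len(inst) - 1
    return {"Q": q, "df": df, "p": float(stats.chi2.sf(q, df))}


def binary_exposure_scale(beta: float, ci: tuple) -> dict:
    """Scale a log-OR and its CI by ln(2) ~ 0.693 to express the effect per
    two-fold increase in the prevalence of a binary exposure."""
    lo, hi = ci
    return {
        "beta": beta * LN2,
        "ci": (lo * LN2, hi * LN2),
        "or": math.exp(beta * LN2),
        "or_ci": (math.exp(lo * LN2), math.exp(hi * LN2)),
    }


def run_mr(inst: InstrumentSet, methods=("ivw", "egger", "wmedian"),
           seed: int = 0) -> dict:
    """Run the requested estimators plus heterogeneity on one instrument set."""
    out = {}
    if "ivw" in methods:
        out["ivw"] = ivw(inst)
    if "egger" in methods and len(inst) >= 3:
        out["egger"] = mr_egger(inst)
    if "wmedian" in methods and len(inst) >= 3:
        out["wmedian"] = weighted_median(inst, seed=seed)
    if len(inst) >= 2:
        out["heterogeneity"] = cochran_q(inst)
    return out
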