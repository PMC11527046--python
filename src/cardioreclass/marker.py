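"""Multiplication-factor incorporation of a novel marker into absolute risk.

A marker with levels k = 0..K (reference level first), per-level prevalence
p_k and hazard ratio HR_k (HR_0 = 1) updates a baseline absolute risk Rbl
while preserving the population mean risk:

    [r]  = sum_k p_k * HR_k          (prevalence-weighted mean hazard ratio)
    R(k) = Rbl * HR_k / [r]

For a binary marker this is [r] = p*HR + (1-p), with multiplication factors
MF(+) = HR/[r] and MF(-) = 1/[r].  The identity sum_k p_k R(k) = Rbl holds
to machine precision for every Rbl.

Prevalences and HRs are handled separately per sex stratum; HRs come from a
covariate-adjusted Cox model on the score-eligible sub-cohort, prevalences
from the same sub-cohort by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import fit_cox

_PTOL = 1e-9


@dataclass
class MarkerUpdateSpec:
    """Ordered marker levels with per-sex prevalences and per-level HRs.

    ``levels``: category labels, reference first.
    ``prevalence``: stratum -> list of p_k (must sum to 1 per stratum).
    ``hazard_ratio``: list of HR_k with HR for the reference level equal 1.
    """

    levels: list
    prevalence: dict
    hazard_ratio: list

    def __post_init__(self):
        if abs(self.hazard_ratio[0] - 1.0) > _PTOL:
            raise ValueError("reference-level hazard ratio must be 1")
        if any(hr <= 0 for hr in self.hazard_ratio):
            raise ValueError("hazard ratios must be > 0")
        if len(self.hazard_ratio) != len(self.levels):
            raise ValueError("one hazard ratio per level required")
        for stratum, p in self.prevalence.items():
            if len(p) != len(self.levels):
                raise ValueError(f"stratum {stratum!r}: one prevalence per level required")
            if abs(sum(p) - 1.0) > _PTOL:
                raise ValueError(f"stratum {stratum!r}: prevalences must sum to 1")


def weighted_mean_risk(spec: MarkerUpdateSpec, stratum: str) -> float:
    """[r] = sum_k p_k * HR_k for the given stratum."""
    p = spec.prevalence[stratum]
    return float(np.dot(p, spec.hazard_ratio))


def update_risk(baseline_risk: float, level, spec: MarkerUpdateSpec, stratum: str) -> float:
    """R(k) = Rbl * HR_k / [r]; capped at 1 with a warning when exceeded."""
    if not (0.0 < baseline_risk < 1.0):
        raise ValueError("baseline risk must lie in (0, 1)")
    k = spec.levels.index(level)
    r = baseline_risk * spec.hazard_ratio[k] / weighted_mean_risk(spec, stratum)
    if r > 1.0:
        warnings.warn("updated risk exceeded 1 and was capped", stacklevel=2)
        return 1.0
    return r


def apply_to_cohort(risks, marker, sex, spec: MarkerUpdateSpec) -> np.ndarray:
    """Vectorised per-row risk update using each row's sex stratum."""
    risks = np.asarray(risks, dtype=float)
    marker = np.asarray(marker)
    sex = np.asarray(sex)
    known = set(spec.levels)
    bad = set(np.unique(marker)) - known
    if bad:
        raise ValueError(f"marker level(s) {sorted(bad)!r} absent from the update spec")
    out = np.empty(len(risks))
    hr = np.array([spec.hazard_ratio[spec.levels.index(m)] for m in marker], dtype=float)
    for s in np.unique(sex):
        m = sex == s
        out[m] = risks[m] * hr[m] / weighted_mean_risk(spec, str(s))
    capped = out > 1.0
    if capped.any():
        warnings.warn(f"{int(capped.sum())} updated risks exceeded 1 and were capped",
                      stacklevel=2)
        out[capped] = 1.0
    return out


def estimate_spec(
    cohort: pd.DataFrame,
    marker_col: str,
    levels: list,
    adjust_cols: list,
    time_col: str = "time_months",
    event_col: str = "event",
    sex_col: str = "sex",
) -> MarkerUpdateSpec:
    """Estimate a MarkerUpdateSpec from a (score-eligible) sub-cohort.

    Hazard ratios per non-reference level come from a single Cox model with
    level indicator variables plus the adjustment covariates; prevalences
    are computed per sex stratum from the same table.
    """
    design = cohort[adjust_cols].copy()
    indicator_cols = []
    for lev in levels[1:]:
        col = f"_marker_{lev}"
        design[col] = (cohort[marker_col] == lev).astype(int)
        indicator_cols.append(col)
    fit = fit_cox(design, cohort[time_col], cohort[event_col])
    hrs = [1.0] + [float(np.exp(fit["log_hr"][c])) for c in indicator_cols]
    prevalence = {}
    for s, sub in cohort.groupby(sex_col):
        counts = np.array([(sub[marker_col] == lev).sum() for lev in levels], dtype=float)
        prevalence[str(s)] = list(counts / counts.sum())
    return MarkerUpdateSpec(levels=list(levels), prevalence=prevalence, hazard_ratio=hrs)
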