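"""Censoring-aware survival primitives.

Kaplan-Meier product-limit estimation, the log-rank test, Harrell's
concordance, a paired-bootstrap C-index difference, and Cox
proportional-hazards fitting.  Time is measured in months throughout.

The Kaplan-Meier estimator and the log-rank statistic are implemented
directly (and cross-checked against lifelines in the test suite); Cox
partial-likelihood maximisation with Efron tie handling delegates to
``lifelines.CoxPHFitter``, and Harrell's C uses ``lifelines.utils
.concordance_index`` (ties in risk score 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit curve: event times (ascending), survival estimates,
    at-risk counts and event counts at each distinct event time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate from right-censored data."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, d = np.unique(t[e == 1], return_counts=True)
    n = len(t)
    # at risk just before u: subjects with t >= u
    at_risk = n - np.searchsorted(t, uniq, side="left")
    surv = np.cumprod(1.0 - d / at_risk) if len(uniq) else np.array([])
    return KMCurve(times=uniq, survival=surv, at_risk=at_risk, n_events=d)


def km_to_frame(curve: KMCurve) -> pd.DataFrame:
    """KM curve as a tidy table (writable as TSV)."""
    return pd.DataFrame({
        "time": curve.times,
        "survival": curve.survival,
        "at_risk": curve.at_risk,
        "n_events": curve.n_events,
    })


def km_at(curve: KMCurve, t) -> float | np.ndarray:
    """Right-continuous step lookup S(t); S(t)=1 before the first event."""
    idx = np.searchsorted(curve.times, np.asarray(t, dtype=float), side="right")
    surv = np.concatenate([[1.0], curve.survival])
    out = surv[idx]
    return float(out) if np.isscalar(t) else out


def km_greenwood_var(curve: KMCurve, t) -> float:
    """Greenwood variance of S(t)."""
    mask = curve.times <= t
    s = km_at(curve, t)
    d, r = curve.n_events[mask], curve.at_risk[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d / (r * (r - d))
    terms = terms[np.isfinite(terms)]
    return float(s**2 * terms.sum())


def logrank_test(groups) -> dict:
    """Log-rank test over k groups of (times, events) pairs.

    Returns the O-E chi-square statistic on k-1 degrees of freedom and its
    p-value.  For two groups the statistic equals the square of the z-form.
    """
    groups = [
        (np.asarray(t, dtype=float), np.asarray(e, dtype=int)) for t, e in groups
    ]
    for t, e in groups:
        if t.size == 0:
            raise ValueError("each group must contain at least one subject")
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    all_t = np.concatenate([t for t, _ in groups])
    all_e = np.concatenate([e for _, e in groups])
    labels = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    event_times = np.unique(all_t[all_e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for u in event_times:
        at_risk = all_t >= u
        n_j = np.array([np.sum(at_risk & (labels == g)) for g in range(k)], dtype=float)
        n = n_j.sum()
        dying = (all_t == u) & (all_e == 1)
        d_j = np.array([np.sum(dying & (labels == g)) for g in range(k)], dtype=float)
        d = d_j.sum()
        observed += d_j
        expected += d * n_j / n
        if n > 1:
            c = d * (n - d) / (n - 1) / n**2
            var += c * (np.diag(n_j * n) - np.outer(n_j, n_j))
    z = (observed - expected)[:-1]
    v = var[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(v) @ z) if z.size else 0.0
    df = k - 1
    return {"chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}


def pairwise_logrank(groups) -> list:
    """All pairwise two-group log-rank tests; returns (i, j, result) triples."""
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            out.append((i, j, logrank_test([groups[i], groups[j]])))
    return out


def harrell_c(risk_scores, times, events) -> float | None:
    """Harrell's concordance: higher risk should sort with earlier events.

    Returns ``None`` when no pairs are comparable (e.g. no events).
    """
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        return None
    # concordance_index expects higher prediction = longer survival
    return float(concordance_index(times, -np.asarray(risk_scores, dtype=float), events))


def cindex_difference(risk_a, risk_b, times, events, n_boot: int = 1000, seed: int = 0) -> dict:
    """Paired bootstrap comparison of two risk scores' Harrell's C.

    delta = C(b) - C(a); percentile CI over individual-level resamples and a
    two-sided p from the bootstrap z (delta / bootstrap SE).
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap intervals", stacklevel=2)
    risk_a = np.asarray(risk_a, dtype=float)
    risk_b = np.asarray(risk_b, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    delta = harrell_c(risk_b, times, events) - harrell_c(risk_a, times, events)
    rng = np.random.default_rng(seed)
    n = len(times)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if events[idx].sum() == 0:
            deltas[b] = 0.0
            continue
        deltas[b] = (harrell_c(risk_b[idx], times[idx], events[idx])
                     - harrell_c(risk_a[idx], times[idx], events[idx]))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    se = deltas.std(ddof=1)
    if se > 0:
        p = float(2 * stats.norm.sf(abs(delta) / se))
    else:
        p = 1.0
    return {"delta": float(delta), "ci": (float(lo), float(hi)), "p": p, "se": float(se)}


def fit_cox(design: pd.DataFrame, times, events) -> dict:
    """Cox proportional-hazards fit (Efron ties, via lifelines).

    ``design`` holds the covariate columns only.  Returns log-HRs, standard
    errors, the partial log-likelihood, and the fitted lifelines object.
    """
    df = design.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as err:  # lifelines raises ConvergenceError and others
        raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    return {
        "log_hr": cph.params_.to_dict(),
        "se": cph.standard_errors_.to_dict(),
        "hr": np.exp(cph.params_).to_dict(),
        "log_likelihood": float(cph.log_likelihood_),
        "model": cph,
    }


def likelihood_ratio_test(fit_null: dict, fit_alt: dict, df: int) -> dict:
    """LRT comparing nested Cox fits (alt must nest null)."""
    stat = 2.0 * (fit_alt["log_likelihood"] - fit_null["log_likelihood"])
    return {"chi2": float(stat), "df": df, "p": float(stats.chi2.sf(max(stat, 0.0), df))}
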