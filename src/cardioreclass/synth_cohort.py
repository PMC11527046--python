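"""Synthetic cohorts and detection fixtures.

Emulates the statistical structure of a population-based carotid-ultrasound
cohort (UK Biobank imaging subsample scale): covariates drawn from published
marginal distributions, plaque presence from a logistic model on those
covariates, plaque count among positives from a fixed level distribution, and
MACE event times from a proportional-hazards (constant baseline hazard) model
with administrative censoring.  Also generates paired ground-truth/predicted
bounding-box fixtures mimicking a held-out detection test set.

Defaults reproduce the study conditions: n=19,499 participants, ~45% plaque
prevalence, ~2% cumulative primary event rate within an 80-month
administrative horizon, and plaque hazard ratios of 1.42 (presence) and
1.30 / 1.62 (one plaque / two-or-more vs none).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

ADMIN_CENSOR_MONTHS = 80.0

#: Table-1-style covariate marginals: mean/SD for continuous, fraction for flags.
DEFAULT_COVARIATE_MEANS = {
    "age": 64.6,
    "sbp": 138.6,
    "total_chol": 5.72,
    "hdl": 1.48,
    "ldl": 3.58,
}
DEFAULT_COVARIATE_SDS = {
    "age": 7.6,
    "sbp": 17.94,
    "total_chol": 1.09,
    "hdl": 0.37,
    "ldl": 0.83,
}
DEFAULT_FRACTIONS = {
    "female": 0.508,
    "smoker_current": 0.036,
    "diabetes": 0.055,
    "statin": 0.237,
    "antihtn": 0.247,
    "prior_cvd": 0.071,
}

# Log-odds per covariate for plaque presence; directions follow the study's
# multivariable logistic model (male sex, age, smoking, SBP, antihypertensive
# use, prior CVD, statins, LDL all positive).  The intercept is solved at
# generation time so that marginal prevalence hits `plaque_prevalence`.
DEFAULT_PLAQUE_LOGODDS = {
    "male": 0.20,
    "age": 0.05,  # per year
    "smoker_current": 0.45,
    "sbp": 0.008,  # per mmHg
    "antihtn": 0.25,
    "prior_cvd": 0.55,
    "statin": 0.40,
    "ldl": 0.12,  # per mmol/L
}

# Log-HRs for the MACE hazard; plaque terms default to the study's adjusted
# count-level estimates.  The baseline rate is solved at generation time so
# that the cumulative event fraction hits `target_event_rate`.
DEFAULT_HAZARD_LOGHR = {
    "age": 0.08,
    "male": 0.45,
    "sbp": 0.012,
    "smoker_current": 0.65,
    "diabetes": 0.50,
    "statin": 0.15,
    "antihtn": 0.20,
    "total_chol": 0.10,
    "hdl": -0.40,
    "prior_cvd": 1.10,
    "plaque_count_1": math.log(1.30),
    "plaque_count_2plus": math.log(1.62),
}

#: Distribution of plaque count among plaque-positive participants.
#: P(1)=0.69 and P(2+)=0.31 reproduce the 45% / 14% cumulative prevalences;
#: 2+ is realised as 2 or 3 with P(3|2+)=3.1/14 matching the 3.1% tail.
COUNT_LEVELS_AMONG_POSITIVE = {1: 0.69, 2: 0.31 * (1 - 3.1 / 14), 3: 0.31 * (3.1 / 14)}

#: MACE component mix among events (MI : stroke : CVD death = 195 : 172 : 63).
EVENT_TYPE_PROBS = {"mi": 195 / 430, "stroke": 172 / 430, "cvd_death": 63 / 430}

COHORT_COLUMNS = [
    "id", "sex", "age", "sbp", "total_chol", "hdl", "ldl",
    "smoker_current", "diabetes", "statin", "antihtn", "prior_cvd",
    "plaque_present", "plaque_count", "time_months", "event", "event_type",
]


@dataclass(frozen=True)
class CohortParams:
    """Generating parameters for a synthetic cohort.

    ``plaque_model`` maps covariate names (plus ``male``) to log-odds;
    its intercept is solved numerically for the requested prevalence.
    ``hazard_model`` maps covariate names — including the derived plaque
    terms ``plaque_present`` / ``plaque_count_1`` / ``plaque_count_2plus`` —
    to log hazard ratios; the baseline rate (events per person-month) is
    solved for the requested cumulative event fraction unless given.
    """

    n_participants: int = 19_499
    covariate_means: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MEANS))
    covariate_sds: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SDS))
    fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    plaque_model: dict = field(default_factory=lambda: dict(DEFAULT_PLAQUE_LOGODDS))
    plaque_prevalence: float = 0.45
    hazard_model: dict = field(default_factory=lambda: dict(DEFAULT_HAZARD_LOGHR))
    base_rate: float | None = None
    target_event_rate: float = 0.022
    count_levels: dict = field(default_factory=lambda: dict(COUNT_LEVELS_AMONG_POSITIVE))
    admin_censor_months: float = ADMIN_CENSOR_MONTHS
    age_range: tuple = (47.0, 83.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name, sd in self.covariate_sds.items():
            if not np.isfinite(sd) or sd <= 0:
                raise ValueError(f"covariate SD for {name!r} must be finite and > 0")
        for name, mu in self.covariate_means.items():
            if not np.isfinite(mu):
                raise ValueError(f"covariate mean for {name!r} must be finite")
        for name, f in self.fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction for {name!r} must lie in [0, 1]")
        for model_name, model in (("plaque_model", self.plaque_model),
                                  ("hazard_model", self.hazard_model)):
            for name, b in model.items():
                if not np.isfinite(b):
                    raise ValueError(f"{model_name} coefficient for {name!r} must be finite")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be > 0")
        if not (0.0 < self.plaque_prevalence < 1.0):
            raise ValueError("plaque_prevalence must lie in (0, 1)")
        if self.base_rate is not None and (not np.isfinite(self.base_rate) or self.base_rate < 0):
            raise ValueError("base_rate must be finite and >= 0")


def _draw_covariates(params: CohortParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_participants
    mu, sd = params.covariate_means, params.covariate_sds
    lo, hi = params.age_range
    a, b = (lo - mu["age"]) / sd["age"], (hi - mu["age"]) / sd["age"]
    cov = {
        "age": stats.truncnorm.rvs(a, b, loc=mu["age"], scale=sd["age"], size=n, random_state=rng),
        "sbp": np.maximum(rng.normal(mu["sbp"], sd["sbp"], n), 70.0),
        "total_chol": np.maximum(rng.normal(mu["total_chol"], sd["total_chol"], n), 1.0),
        "hdl": np.maximum(rng.normal(mu["hdl"], sd["hdl"], n), 0.3),
        "ldl": np.maximum(rng.normal(mu["ldl"], sd["ldl"], n), 0.3),
    }
    for name, f in params.fractions.items():
        cov[name] = (rng.random(n) < f).astype(np.int64)
    df = pd.DataFrame(cov)
    df["male"] = 1 - df["female"]
    return df


def _linear_predictor(df: pd.DataFrame, coefs: dict) -> np.ndarray:
    lp = np.zeros(len(df))
    for name, b in coefs.items():
        if name not in df.columns:
            raise KeyError(f"model term {name!r} not found among generated covariates")
        lp += b * df[name].to_numpy(dtype=float)
    return lp


def _solve_logit_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + lp)) == target."""
    f = lambda b0: special.expit(b0 + lp).mean() - target
    return optimize.brentq(f, -50.0, 50.0)


def _solve_base_rate(hr: np.ndarray, horizon: float, target: float) -> float:
    """Baseline rate r with mean(1 - exp(-r * hr * horizon)) == target."""
    f = lambda log_r: np.mean(1.0 - np.exp(-np.exp(log_r) * hr * horizon)) - target
    return math.exp(optimize.brentq(f, -30.0, 5.0))


def generate_cohort(params: CohortParams | None = None, **overrides) -> pd.DataFrame:
    """Generate a synthetic cohort table.

    Returns a DataFrame with one row per participant: covariates, plaque
    phenotype (presence flag and count with levels 0/1/2/3), observed
    follow-up time in months, event indicator, and MACE component type.
    Deterministic given ``params.seed``.
    """
    if params is None:
        params = CohortParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)
    df = _draw_covariates(params, rng)

    # plaque presence: logistic on covariates, intercept solved for prevalence
    lp_plaque = _linear_predictor(df, params.plaque_model)
    b0 = _solve_logit_intercept(lp_plaque, params.plaque_prevalence)
    p_plaque = special.expit(b0 + lp_plaque)
    plaque = rng.random(len(df)) < p_plaque

    levels = np.array(sorted(params.count_levels))
    probs = np.array([params.count_levels[k] for k in levels], dtype=float)
    probs = probs / probs.sum()
    count = np.zeros(len(df), dtype=np.int64)
    count[plaque] = rng.choice(levels, size=int(plaque.sum()), p=probs)
    df["plaque_present"] = plaque.astype(np.int64)
    df["plaque_count"] = count
    df["plaque_count_1"] = (count == 1).astype(np.int64)
    df["plaque_count_2plus"] = (count >= 2).astype(np.int64)

    # event times: exponential with rate = base_rate * exp(sum log-HR * x)
    lp_hazard = _linear_predictor(df, params.hazard_model)
    horizon = params.admin_censor_months
    if params.base_rate is not None:
        rel_hazard = np.exp(lp_hazard)
        base_rate = params.base_rate
    else:
        # centering is absorbed into the solved baseline rate
        rel_hazard = np.exp(lp_hazard - lp_hazard.mean())
        base_rate = _solve_base_rate(rel_hazard, horizon, params.target_event_rate)
    rate = base_rate * rel_hazard
    with np.errstate(divide="ignore"):
        t_event = np.where(rate > 0, rng.exponential(1.0, len(df)) / np.where(rate > 0, rate, 1.0), np.inf)
    event = t_event <= horizon
    df["time_months"] = np.where(event, t_event, horizon)
    df["event"] = event.astype(np.int64)
    types = np.array(list(EVENT_TYPE_PROBS))
    type_p = np.array(list(EVENT_TYPE_PROBS.values()))
    df["event_type"] = "none"
    df.loc[event, "event_type"] = rng.choice(types, size=int(event.sum()), p=type_p)

    df.insert(0, "id", np.arange(1, len(df) + 1))
    df["sex"] = np.where(df["female"] == 1, "female", "male")
    return df[COHORT_COLUMNS + ["plaque_count_1", "plaque_count_2plus"]]


# ---------------------------------------------------------------------------
# detection fixtures
# ---------------------------------------------------------------------------

CANVAS_W, CANVAS_H = 480, 448  # ultrasound crop size in pixels


def generate_detection_fixtures(
    n_images: int = 103,
    pos_fraction: float = 38 / 103,
    boxes_per_positive: tuple = (0.75, 0.2, 0.05),
    jitter: float = 4.0,
    fp_rate: float = 0.07,
    fn_rate: float = 0.10,
    seed: int = 0,
):
    """Generate paired ground-truth annotations and noisy predictions.

    Emulates a blind detection test set: ``pos_fraction`` of images carry
    1..k true plaque boxes (``boxes_per_positive`` gives P(1), P(2), ...);
    predictions are jittered copies of true boxes with misses removed at
    ``fn_rate``, plus spurious boxes appearing on any image at ``fp_rate``,
    each prediction carrying a confidence in (0, 1].

    Returns ``(annotations, predictions)``: two lists of per-image records
    ``{"image_id": str, "boxes": [{"x_min", "y_min", "x_max", "y_max",
    ("confidence")}]}``.  Jitter that would collapse a box to zero area drops
    the box (counted as a miss).
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_images * pos_fraction))
    probs = np.asarray(boxes_per_positive, dtype=float)
    probs = probs / probs.sum()
    annotations, predictions = [], []
    for i in range(n_images):
        image_id = f"img_{i:04d}"
        gt_boxes = []
        if i < n_pos:
            k = int(rng.choice(np.arange(1, len(probs) + 1), p=probs))
            for _ in range(k):
                w = rng.uniform(30, 120)
                h = rng.uniform(20, 80)
                x0 = rng.uniform(0, CANVAS_W - w)
                y0 = rng.uniform(0, CANVAS_H - h)
                gt_boxes.append({"x_min": x0, "y_min": y0, "x_max": x0 + w, "y_max": y0 + h})
        pred_boxes = []
        for box in gt_boxes:
            if rng.random() < fn_rate:
                continue
            j = rng.normal(0.0, jitter, size=4) if jitter > 0 else np.zeros(4)
            cand = {
                "x_min": max(box["x_min"] + j[0], 0.0),
                "y_min": max(box["y_min"] + j[1], 0.0),
                "x_max": min(box["x_max"] + j[2], float(CANVAS_W)),
                "y_max": min(box["y_max"] + j[3], float(CANVAS_H)),
            }
            if cand["x_max"] <= cand["x_min"] or cand["y_max"] <= cand["y_min"]:
                continue  # degenerate after jitter: dropped
            cand["confidence"] = float(rng.uniform(0.3, 1.0))
            pred_boxes.append(cand)
        if rng.random() < fp_rate:
            w = rng.uniform(25, 90)
            h = rng.uniform(15, 60)
            x0 = rng.uniform(0, CANVAS_W - w)
            y0 = rng.uniform(0, CANVAS_H - h)
            pred_boxes.append({
                "x_min": x0, "y_min": y0, "x_max": x0 + w, "y_max": y0 + h,
                "confidence": float(rng.uniform(0.13, 0.6)),
            })
        annotations.append({"image_id": image_id, "boxes": gt_boxes})
        predictions.append({"image_id": image_id, "boxes": pred_boxes})
    return annotations, predictions
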