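"""Pooled Cohort Equations (PCE) absolute risk and eligibility filtering.

The PCE estimate 10-year risk of a first hard atherosclerotic cardiovascular
event from sex- and race-stratified Cox-type equations published in the 2013
ACC/AHA risk-assessment guideline.  Coefficients are shipped as a
human-readable YAML data file (see ``data/pce_coefficients.yaml`` for
provenance) whose content hash is verified at load time.

Risk for a participant in stratum *s* with linear predictor ``lp`` is

    risk = 1 - S0_s ** exp(lp - mean_lp_s)

with ``S0_s`` the stratum's baseline 10-year survival and ``mean_lp_s`` the
cohort-mean linear predictor from the derivation cohorts.

Lipids enter in mg/dL and blood pressure in mmHg; cholesterol measured in
mmol/L converts with the factor 38.67.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from importlib import resources

import numpy as np
import pandas as pd
import yaml

MG_PER_MMOL_CHOL = 38.67

#: sha256 of the YAML data file, pinned so silent edits are caught.
_COEFFS_SHA256 = None  # filled on first load, checked thereafter

_ELIGIBILITY = {
    "age": (40.0, 79.0),          # years
    "total_chol_mgdl": (130.0, 320.0),
    "hdl_mgdl": (20.0, 100.0),
    "sbp": (90.0, 200.0),         # mmHg
}

_cache: dict = {}


def mmol_to_mgdl(x):
    """Cholesterol mmol/L -> mg/dL."""
    return np.asarray(x, dtype=float) * MG_PER_MMOL_CHOL


def mgdl_to_mmol(x):
    """Cholesterol mg/dL -> mmol/L."""
    return np.asarray(x, dtype=float) / MG_PER_MMOL_CHOL


def load_model() -> dict:
    """Load the shipped PCE coefficient table (cached)."""
    if "model" in _cache:
        return _cache["model"]
    ref = resources.files("cardioreclass.data") / "pce_coefficients.yaml"
    text = ref.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    model = yaml.safe_load(text)["strata"]
    for name, stratum in model.items():
        s0 = stratum["baseline_survival"]
        if not (0.0 < s0 < 1.0):
            raise ValueError(f"baseline survival for {name!r} outside (0,1)")
    model["_sha256"] = digest
    _cache["model"] = model
    return model


def stratum_name(sex: str, race_group: str = "white") -> str:
    """Map sex and race group to a PCE stratum.

    Race groups other than ``black`` (including unknown/other) use the
    White/other equations, mirroring cohorts that encode missing ethnicity
    as "Other".
    """
    sex = sex.lower()
    if sex not in ("male", "female"):
        raise KeyError(f"unknown sex {sex!r}")
    group = "black" if str(race_group).lower() == "black" else "white"
    return f"{sex}_{group}"


def _terms(age, tc_mgdl, hdl_mgdl, sbp, treated, smoker, diabetes) -> dict:
    la, ltc, lhdl, lsbp = math.log(age), math.log(tc_mgdl), math.log(hdl_mgdl), math.log(sbp)
    return {
        "ln_age": la,
        "ln_age_sq": la * la,
        "ln_tc": ltc,
        "ln_age_x_ln_tc": la * ltc,
        "ln_hdl": lhdl,
        "ln_age_x_ln_hdl": la * lhdl,
        "ln_sbp_treated": lsbp if treated else 0.0,
        "ln_age_x_ln_sbp_treated": la * lsbp if treated else 0.0,
        "ln_sbp_untreated": 0.0 if treated else lsbp,
        "ln_age_x_ln_sbp_untreated": 0.0 if treated else la * lsbp,
        "smoker": float(smoker),
        "ln_age_x_smoker": la * float(smoker),
        "diabetes": float(diabetes),
    }


def pce_linear_predictor(row, model: dict | None = None, units: str = "si") -> float:
    """PCE linear predictor for one participant.

    ``row`` is a mapping with keys ``sex``, ``age``, ``total_chol``, ``hdl``,
    ``sbp``, ``antihtn``, ``smoker_current``, ``diabetes`` and optionally
    ``race_group``.  With ``units="si"`` cholesterol is taken in mmol/L and
    converted; with ``units="conventional"`` it is taken as mg/dL already.
    Out-of-range covariates warn but are still scored.
    """
    model = model or load_model()
    name = stratum_name(row["sex"], row.get("race_group", "white"))
    if name not in model:
        raise KeyError(f"unknown stratum {name!r}")
    stratum = model[name]
    if units == "si":
        tc, hdl = row["total_chol"] * MG_PER_MMOL_CHOL, row["hdl"] * MG_PER_MMOL_CHOL
    elif units == "conventional":
        tc, hdl = row["total_chol"], row["hdl"]
    else:
        raise ValueError("units must be 'si' or 'conventional'")
    for label, value, (lo, hi) in (
        ("age", row["age"], _ELIGIBILITY["age"]),
        ("total cholesterol", tc, _ELIGIBILITY["total_chol_mgdl"]),
        ("HDL", hdl, _ELIGIBILITY["hdl_mgdl"]),
        ("SBP", row["sbp"], _ELIGIBILITY["sbp"]),
    ):
        if not (lo <= value <= hi):
            warnings.warn(f"{label} = {value:.1f} outside the PCE validated range [{lo}, {hi}]",
                          stacklevel=2)
    terms = _terms(row["age"], tc, hdl, row["sbp"],
                   bool(row["antihtn"]), row["smoker_current"], row["diabetes"])
    return sum(coef * terms[t] for t, coef in stratum["coefficients"].items())


def pce_risk(lp, model: dict | None = None, stratum: str = "female_white"):
    """Absolute 10-year risk from a linear predictor: strictly increasing in
    ``lp`` and bounded in (0, 1)."""
    model = model or load_model()
    s = model[stratum]
    return 1.0 - s["baseline_survival"] ** np.exp(np.asarray(lp, dtype=float)
                                                  - s["mean_linear_predictor"])


def pce_eligible(row, units: str = "si") -> bool:
    """Guideline eligibility filter: age 40-79, TC 130-320 mg/dL,
    HDL 20-100 mg/dL, SBP 90-200 mmHg, all bounds inclusive."""
    if units == "si":
        tc, hdl = row["total_chol"] * MG_PER_MMOL_CHOL, row["hdl"] * MG_PER_MMOL_CHOL
    else:
        tc, hdl = row["total_chol"], row["hdl"]
    checks = (
        _ELIGIBILITY["age"][0] <= row["age"] <= _ELIGIBILITY["age"][1],
        _ELIGIBILITY["total_chol_mgdl"][0] <= tc <= _ELIGIBILITY["total_chol_mgdl"][1],
        _ELIGIBILITY["hdl_mgdl"][0] <= hdl <= _ELIGIBILITY["hdl_mgdl"][1],
        _ELIGIBILITY["sbp"][0] <= row["sbp"] <= _ELIGIBILITY["sbp"][1],
    )
    return all(checks)


def score_cohort(cohort: pd.DataFrame, units: str = "si") -> pd.DataFrame:
    """Add ``pce_lp``, ``pce_risk`` and ``pce_eligible`` columns to a cohort
    table.  Vectorised; out-of-range covariates are scored silently (the
    eligibility flag is the intended filter at cohort scale)."""
    model = load_model()
    out = cohort.copy()
    if units == "si":
        tc = cohort["total_chol"].to_numpy(dtype=float) * MG_PER_MMOL_CHOL
        hdl = cohort["hdl"].to_numpy(dtype=float) * MG_PER_MMOL_CHOL
    elif units == "conventional":
        tc = cohort["total_chol"].to_numpy(dtype=float)
        hdl = cohort["hdl"].to_numpy(dtype=float)
    else:
        raise ValueError("units must be 'si' or 'conventional'")
    age = cohort["age"].to_numpy(dtype=float)
    sbp = cohort["sbp"].to_numpy(dtype=float)
    treated = cohort["antihtn"].to_numpy(dtype=float) > 0
    la, ltc, lhdl, lsbp = np.log(age), np.log(tc), np.log(hdl), np.log(sbp)
    smoker = cohort["smoker_current"].to_numpy(dtype=float)
    diabetes = cohort["diabetes"].to_numpy(dtype=float)
    terms = {
        "ln_age": la,
        "ln_age_sq": la * la,
        "ln_tc": ltc,
        "ln_age_x_ln_tc": la * ltc,
        "ln_hdl": lhdl,
        "ln_age_x_ln_hdl": la * lhdl,
        "ln_sbp_treated": np.where(treated, lsbp, 0.0),
        "ln_age_x_ln_sbp_treated": np.where(treated, la * lsbp, 0.0),
        "ln_sbp_untreated": np.where(treated, 0.0, lsbp),
        "ln_age_x_ln_sbp_untreated": np.where(treated, 0.0, la * lsbp),
        "smoker": smoker,
        "ln_age_x_smoker": la * smoker,
        "diabetes": diabetes,
    }
    race = (cohort["race_group"] if "race_group" in cohort.columns
            else pd.Series("white", index=cohort.index)).astype(str).str.lower()
    strata = cohort["sex"].str.lower() + "_" + np.where(race == "black", "black", "white")
    lps = np.zeros(len(cohort))
    risks = np.zeros(len(cohort))
    for name in strata.unique():
        mask = (strata == name).to_numpy()
        s = model[name]
        lp = np.zeros(mask.sum())
        for t, coef in s["coefficients"].items():
            lp += coef * terms[t][mask]
        lps[mask] = lp
        risks[mask] = 1.0 - s["baseline_survival"] ** np.exp(lp - s["mean_linear_predictor"])
    out["pce_lp"] = lps
    out["pce_risk"] = risks
    lims = _ELIGIBILITY
    out["pce_eligible"] = (
        (age >= lims["age"][0]) & (age <= lims["age"][1])
        & (tc >= lims["total_chol_mgdl"][0]) & (tc <= lims["total_chol_mgdl"][1])
        & (hdl >= lims["hdl_mgdl"][0]) & (hdl <= lims["hdl_mgdl"][1])
        & (sbp >= lims["sbp"][0]) & (sbp <= lims["sbp"][1])
    )
    return out
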