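"""End-to-end analysis pipeline.

Orchestrates: synthesize cohort -> PCE scoring and eligibility ->
sex-stratified recalibration -> Eq.-1 marker integration (plaque presence
and count) -> reclassification and model-comparison statistics ->
descriptive summaries, writing plain-text artifacts (TSV/JSON) plus a run
log with seeds and content digests.  A single global seed is fanned out to
per-stage child seeds through ``numpy.random.SeedSequence.spawn`` so each
stage is reproducible standalone.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, descriptive, io, marker, pce, reclassification, survival
from .synth_cohort import CohortParams, generate_cohort

ADJUST_COLS = ["age", "female", "sbp", "smoker_current", "diabetes",
               "antihtn", "total_chol", "hdl", "statin"]

#: Adjustment set matching the synthetic generator's full hazard covariates;
#: used for parameter-recovery experiments where the fitted Cox model must
#: be correctly specified.
FULL_ADJUST_COLS = ADJUST_COLS + ["prior_cvd"]

DEFAULT_CONFIG = {
    "seed": 0,
    "n_participants": 19_499,
    "horizon_months": 80.0,
    "threshold": 0.075,
    "n_boot": 1000,
    "mr_instruments_tsv": None,
}


def stage_seeds(seed: int, n_stages: int = 8) -> list:
    """Fan a global seed out to per-stage child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_stages)]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | None = None, outdir="results/pipeline") -> dict:
    """Run the full analysis; returns the report dict and writes artifacts."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg["seed"])
    log: list = []
    t_start = time.time()

    def _log(stage, **kw):
        log.append({"stage": stage, "elapsed_s": round(time.time() - t_start, 2), **kw})

    try:
        # 1. synthesize
        extra = {k: cfg[k] for k in ("hazard_model", "plaque_model", "target_event_rate")
                 if cfg.get(k) is not None}
        params = CohortParams(n_participants=cfg["n_participants"], seed=seeds[0], **extra)
        cohort = generate_cohort(params)
        cohort_path = outdir / "cohort.tsv"
        io.write_cohort_tsv(cohort, cohort_path)
        io.write_params_yaml(params, outdir / "cohort_params.yaml")
        _log("synthesize", n=len(cohort), digest=_digest(cohort_path))

        # 2. PCE scoring + eligibility
        cohort = pce.score_cohort(cohort)
        cohort["female"] = (cohort["sex"] == "female").astype(int)
        eligible = cohort[cohort["pce_eligible"]].reset_index(drop=True)
        _log("pce", n_eligible=len(eligible))

        # 3. recalibration of the PCE linear predictor, stratified by sex
        t0 = cfg["horizon_months"]
        recal = calibration.recalibrate(eligible["pce_lp"], eligible["time_months"],
                                        eligible["event"], eligible["sex"], t0=t0)
        eligible["risk_recal"] = recal["risk"]
        gnd = calibration.gnd_test(eligible["risk_recal"], eligible["time_months"],
                                   eligible["event"], t0=t0)
        ici_val = calibration.ici(eligible["risk_recal"], eligible["time_months"],
                                  eligible["event"], t0=t0)
        calibration.calibration_plot_data(
            eligible["risk_recal"], eligible["time_months"], eligible["event"], t0=t0
        ).to_csv(outdir / "calibration.tsv", sep="\t", index=False)
        _log("recalibrate", slope=recal["beta"], gnd_p=gnd["p"], ici=ici_val)

        # 4. marker integration (Eq. 1) for presence and count
        count_level = np.minimum(eligible["plaque_count"], 2)  # 0 / 1 / 2+
        eligible["plaque_level"] = count_level
        spec_presence = marker.estimate_spec(
            eligible.assign(marker=eligible["plaque_present"]), "marker",
            levels=[0, 1], adjust_cols=ADJUST_COLS)
        spec_count = marker.estimate_spec(
            eligible.assign(marker=count_level), "marker",
            levels=[0, 1, 2], adjust_cols=ADJUST_COLS)
        eligible["risk_presence"] = marker.apply_to_cohort(
            eligible["risk_recal"], eligible["plaque_present"], eligible["sex"], spec_presence)
        eligible["risk_count"] = marker.apply_to_cohort(
            eligible["risk_recal"], count_level, eligible["sex"], spec_count)
        _log("marker", hr_presence=spec_presence.hazard_ratio[1],
             hr_count=spec_count.hazard_ratio)

        # 5. reclassification + model comparison
        nb = cfg["n_boot"]
        report_metrics = {}
        for label, col in (("presence", "risk_presence"), ("count", "risk_count")):
            table = reclassification.build_reclass_table(
                eligible["risk_recal"], eligible[col], eligible["time_months"],
                eligible["event"], t0, thresholds=[cfg["threshold"]])
            nri = reclassification.categorical_nri(table)
            cfnri = reclassification.cf_nri(
                eligible["risk_recal"].to_numpy(), eligible[col].to_numpy(),
                eligible["time_months"].to_numpy(), eligible["event"].to_numpy(),
                t0, n_boot=nb, seed=seeds[4])
            idi_res = reclassification.idi(
                eligible["risk_recal"].to_numpy(), eligible[col].to_numpy(),
                eligible["time_months"].to_numpy(), eligible["event"].to_numpy(),
                t0, n_boot=nb, seed=seeds[5])
            pd.DataFrame(
                np.vstack([table.controls, table.cases]),
                columns=[f"new_cat{j}" for j in range(table.cases.shape[1])],
                index=[f"controls_old{j}" for j in range(table.controls.shape[0])]
                + [f"cases_old{j}" for j in range(table.cases.shape[0])],
            ).to_csv(outdir / f"reclass_table_{label}.tsv", sep="\t")
            report_metrics[label] = {
                "categorical_nri": nri, "cfnri": cfnri, "idi": idi_res,
                "n_cases": table.n_cases, "n_controls": table.n_controls,
            }
        cidx = survival.cindex_difference(
            eligible["risk_recal"].to_numpy(), eligible["risk_presence"].to_numpy(),
            eligible["time_months"].to_numpy(), eligible["event"].to_numpy(),
            n_boot=min(nb, 200), seed=seeds[6])
        report_metrics["cindex_presence_vs_base"] = cidx
        _log("reclassify", **{k: v["categorical_nri"]["nri"]
                              for k, v in report_metrics.items() if "categorical_nri" in v})

        # 6. descriptive summaries
        prev = descriptive.prevalence_table(cohort)
        prev.to_csv(outdir / "prevalence.tsv", sep="\t", index=False)
        male = cohort[cohort["sex"] == "male"]
        female = cohort[cohort["sex"] == "female"]
        sex_test = descriptive.two_proportion_z(
            int(male["plaque_present"].sum()), len(male),
            int(female["plaque_present"].sum()), len(female))
        _log("describe", overall_prevalence=float(cohort["plaque_present"].mean()),
             sex_z=sex_test["z"])

        # 7. optional MR on supplied summary statistics
        mr_results = None
        if cfg.get("mr_instruments_tsv"):
            from .mr import InstrumentSet, run_mr
            inst = InstrumentSet.from_tsv(cfg["mr_instruments_tsv"])
            mr_results = run_mr(inst, seed=seeds[7])
            _log("mr", k=len(inst))
    except Exception as err:
        stage = log[-1]["stage"] if log else "init"
        raise RuntimeError(f"pipeline aborted after stage {stage!r}: {err}") from err

    report = {
        "config": {k: v for k, v in cfg.items()},
        "seeds": seeds,
        "metrics": report_metrics,
        "recalibration": {"slope": recal["beta"], "gnd": {k: gnd[k] for k in ("chi2", "df", "p")},
                          "ici": ici_val},
        "prevalence_overall": float(cohort["plaque_present"].mean()),
        "mr": mr_results,
        "log": log,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=_jsonify))
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    return report


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
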