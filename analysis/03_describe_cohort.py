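"""Descriptive epidemiology of the synthetic cohort.

Prevalence by sex and age band (Wilson CIs), the sex comparison
(two-proportion z), the age trend (Cochran-Armitage), and the multivariable
logistic model for plaque presence with per-SD odds ratios.
Reads results/cohort.tsv (written by 01_simulate_cohort.py).
"""

import json
from pathlib import Path

from cardioreclass import descriptive, io

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    cohort = io.read_cohort_tsv(OUT / "cohort.tsv")
    cohort["female"] = (cohort["sex"] == "female").astype(int)
    cohort["male"] = 1 - cohort["female"]

    prev = descriptive.prevalence_table(cohort)
    prev.to_csv(OUT / "prevalence_by_sex_age.tsv", sep="\t", index=False)

    male = cohort[cohort["sex"] == "male"]
    female = cohort[cohort["sex"] == "female"]
    sex_test = descriptive.two_proportion_z(
        int(male["plaque_present"].sum()), len(male),
        int(female["plaque_present"].sum()), len(female))

    band_tab = descriptive.prevalence_table(cohort, by=("age_band",))
    ordered = band_tab.set_index("age_band").loc[["45-54", "55-64", "65-74", ">=75"]]
    trend = descriptive.cochran_armitage(ordered["x"].tolist(), ordered["n"].tolist())

    covars = ["male", "age", "smoker_current", "sbp", "antihtn",
              "prior_cvd", "statin", "ldl"]
    logit = descriptive.fit_logistic(cohort[covars], cohort["plaque_present"])

    out = {
        "overall_prevalence": float(cohort["plaque_present"].mean()),
        "male_prevalence": float(male["plaque_present"].mean()),
        "female_prevalence": float(female["plaque_present"].mean()),
        "sex_two_proportion_z": sex_test,
        "age_trend_cochran_armitage": trend,
        "logistic_or_per_sd": logit["odds_ratio"],
    }
    (OUT / "descriptive.json").write_text(json.dumps(out, indent=1))
    print(f"plaque prevalence: overall {out['overall_prevalence']:.3f}, "
          f"male {out['male_prevalence']:.3f} vs female {out['female_prevalence']:.3f} "
          f"(z = {sex_test['z']:.1f}, p = {sex_test['p']:.2e})")
    print(f"age trend p = {trend['p']:.2e}")
    print("odds ratios (per SD for continuous):")
    for k, v in logit["odds_ratio"].items():
        print(f"  {k:15s} {v:.2f}")


if __name__ == "__main__":
    main()
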