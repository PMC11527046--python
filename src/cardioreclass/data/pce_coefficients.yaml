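# Pooled Cohort Equations coefficient table.
#
# Provenance: transcribed from the 2013 ACC/AHA Guideline on the Assessment
# of Cardiovascular Risk (Goff DC Jr et al., Circulation 2014;129:S49-S73),
# Appendix 7, Table A ("Equation Parameters of the Pooled Cohort Equations
# for Estimation of 10-Year Risk of Hard ASCVD").
#
# Terms per stratum: coefficient * transformed covariate, where the
# transforms are ln(age), ln(age)^2, ln(total cholesterol mg/dL),
# ln(HDL mg/dL), ln(SBP mmHg) split by antihypertensive treatment, current
# smoking and diabetes flags, and the listed products.  The 10-year risk is
# 1 - S0 ^ exp(lp - mean_lp).
#
# sha256 of the strata block is recorded in pce.py and checked at load.
strata:
  female_black:
    coefficients:
      ln_age: 17.114
      ln_tc: 0.940
      ln_hdl: -18.920
      ln_age_x_ln_hdl: 4.475
      ln_sbp_treated: 29.291
      ln_age_x_ln_sbp_treated: -6.432
      ln_sbp_untreated: 27.820
      ln_age_x_ln_sbp_untreated: -6.087
      smoker: 0.691
      diabetes: 0.874
    mean_linear_predictor: 86.61
    baseline_survival: 0.9533
  female_white:
    coefficients:
      ln_age: -29.799
      ln_age_sq: 4.884
      ln_tc: 13.540
      ln_age_x_ln_tc: -3.114
      ln_hdl: -13.578
      ln_age_x_ln_hdl: 3.149
      ln_sbp_treated: 2.019
      ln_sbp_untreated: 1.957
      smoker: 7.574
      ln_age_x_smoker: -1.665
      diabetes: 0.661
    mean_linear_predictor: -29.18
    baseline_survival: 0.9665
  male_black:
    coefficients:
      ln_age: 2.469
      ln_tc: 0.302
      ln_hdl: -0.307
      ln_sbp_treated: 1.916
      ln_sbp_untreated: 1.809
      smoker: 0.549
      diabetes: 0.645
    mean_linear_predictor: 19.54
    baseline_survival: 0.8954
  male_white:
    coefficients:
      ln_age: 12.344
      ln_tc: 11.853
      ln_age_x_ln_tc: -2.664
      ln_hdl: -7.990
      ln_age_x_ln_hdl: 1.769
      ln_sbp_treated: 1.797
      ln_sbp_untreated: 1.764
      smoker: 7.837
      ln_age_x_smoker: -1.795
      diabetes: 0.658
    mean_linear_predictor: 61.18
    baseline_survival: 0.9144
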