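# Methods

`cardioreclass` implements the statistical pipeline behind a population-scale
carotid-plaque study: generating cohorts with the structure such a study
assumes, evaluating a bounding-box plaque detector, scoring and recalibrating
absolute cardiovascular risk, folding a plaque phenotype into that risk, and
quantifying what the phenotype adds. This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic experiments do and do not establish.

## Synthetic cohort model

The generator (`synth_cohort`) draws one row per participant:

1. **Covariates.** Independent marginals matched to the cohort's descriptive
   table: age ~ truncated normal (mean 64.6, SD 7.6 y, support 47–83), SBP
   ~ N(138.6, 17.94) mmHg, total cholesterol ~ N(5.72, 1.09) and HDL
   ~ N(1.48, 0.37) mmol/L, LDL ~ N(3.58, 0.83) mmol/L, and Bernoulli flags
   (female 0.508, current smoking 0.036, diabetes 0.055, statin 0.237,
   antihypertensive use 0.247, prior CVD 0.071). Continuous draws are
   floor-clipped at physiologic minima. No covariance structure is imposed
   (only marginals are published); a correlation hook was considered and
   deliberately omitted rather than inventing a covariance matrix.
2. **Plaque phenotype.** Presence follows a logistic model whose slopes point
   the way the observed risk-factor associations point (age 0.05/y, male 0.20,
   current smoking 0.45, SBP 0.008/mmHg, antihypertensive use 0.25, prior CVD
   0.55, statin 0.40, LDL 0.12/mmol/L); the intercept is solved numerically at
   generation time so that marginal prevalence equals the target (default
   45%). Among positives the count is 1 with probability 0.69 and 2+ with
   0.31, the 2+ mass split 2:3 so the cumulative prevalences reproduce
   45% / 14% / 3.1% for ≥1 / ≥2 / ≥3 plaques.
3. **Outcomes.** Event times are exponential under proportional hazards:
   rate = base_rate × exp(Σ β·x), with plaque count levels entering at
   log 1.30 (one plaque) and log 1.62 (two or more) by default, alongside
   conventional risk-factor effects. The baseline rate is solved so that the
   expected cumulative event fraction by the 80-month administrative horizon
   equals 2.2%. Observed time is min(event time, 80 months); there is a
   single censoring stream (administrative), a deliberate simplification of
   competing non-CVD death. Events are labelled MI / stroke / CVD death in
   proportion 195:172:63. A constant baseline hazard suffices because every
   estimand studied here (Cox coefficients, KM contrasts, reclassification at
   a fixed horizon) depends on the proportional-hazards structure, not the
   baseline shape.

Because covariates are independent and the marginals are the published ones,
passing parameter-recovery tests demonstrates correctness of the estimators
under the stated model — not realism of any real cohort's joint distribution,
nor its censoring pattern (real follow-up ends at staggered dates; we censor
everyone at 80 months).

## Detection evaluation

Boxes are half-open pixel rectangles with origin top-left, so areas and IoU
are exact rational arithmetic. Matching is COCO-style greedy: discard
predictions below the confidence threshold (default 0.13), then visit
survivors in descending confidence, each taking its highest-IoU unmatched
ground-truth box with IoU ≥ 0.5. Greedy matching can in principle fall short
of the optimal assignment, but a brute-force oracle confirms equality of
match cardinality across 1,000 random instances with ≤3 boxes per side.
AP@50 uses all-point interpolation (precision envelope integrated over
recall steps); framework defaults vary (some use 101-point sampling), which
is why the worked examples pin the convention. Threshold tuning maximises
the unweighted mean of image-level accuracy, sensitivity and specificity —
"optimise and balance" made concrete — with ties resolved to the lowest
threshold. Per-individual phenotypes select one image per artery (preferring
plaque-positive images, seeded-random among several positives) and sum box
counts over arteries.

## PCE risk and recalibration

The pooled cohort equations ship as a YAML table (four sex × race strata;
provenance in the file header) with a content hash checked at load. Risk is
`1 − S0^exp(lp − mean_lp)`. Unknown or missing race uses the White/other
stratum. Eligibility is the guideline window: age 40–79, TC 130–320 mg/dL,
HDL 20–100 mg/dL, SBP 90–200 mmHg, all bounds inclusive. SI lipids convert
at 38.67 mg/dL per mmol/L. The transcription was validated against the
guideline's published worked examples; for the white-male profile our
full-precision computation gives 5.4% where the source prints 5.3%, a known
artifact of the source's intermediate rounding.

Recalibration fits a sex-stratified Cox model with the PCE linear predictor
as sole covariate (the slope is reported, making miscalibration of ordering
visible) and rebuilds risk from the Breslow baseline cumulative hazard per
stratum at a configurable horizon, default 80 months. The linear predictor
is mean-centred within stratum before fitting — a pure reparameterisation
absorbed by the stratum baseline, needed because raw PCE predictors sit at
stratum-specific levels near −29 and +61 and derail the optimizer otherwise.
The 7.5% decision threshold is applied to these 80-month recalibrated risks
even though it is defined for 10-year risk, mirroring the study design being
reproduced.

**Calibration assessment.** The GND statistic groups subjects into deciles
of predicted risk and sums (observed − mean predicted)²/Greenwood-variance,
with observed risk the KM complement at the horizon; groups with fewer than
5 events merge upward. Because predictions are externally specified, each
usable group contributes an independent ~χ²₁ term, so the reference
distribution uses df = number of groups (verified by null simulation; with
df = G−1 the test is anticonservative). Each group's term is a Wald
statistic with estimated variance, so the χ² reference is asymptotic: with
fewer than ~50 events per decile the test rejects somewhat above nominal,
which is inherent to the statistic, not to this implementation. The ICI is
the mean absolute gap between predicted risk and a smoothed observed risk,
the smoother being locally weighted linear regression (span 0.5, robustness
iterations disabled — they would treat the near-binary pseudo-observations
as outliers) of jackknife KM pseudo-observations of event status at the
horizon. Constant predictions reduce to |mean pseudo-observation − pred|.

## Marker integration (multiplication-factor method)

For marker levels k with prevalences p_k and hazard ratios HR_k (reference
HR = 1), the prevalence-weighted mean hazard ratio is [r] = Σ p_k·HR_k and
the updated risk is R(k) = Rbl·HR_k/[r], capped at 1 with a warning. This is
the unique reading of the source equation block (whose printed form is
garbled) consistent with MF(+) = HR/[r] and with conservation of the
population mean risk, which holds to machine precision and is enforced by a
property test. Prevalences and HRs are sex-specific; HRs come from a Cox
model on the score-eligible sub-cohort adjusted for sex, age, HDL and total
cholesterol, antihypertensive use, smoking, SBP and statin use, and
prevalences from the same sub-cohort (whether the original analysis used the
eligible or full cohort for prevalence is unknowable from the text; eligible
is the default and both are reachable through `estimate_spec`).

## Reclassification statistics

Categorical tables at the 7.5% threshold classify cases (event by the
horizon) and controls (followed event-free past it); subjects censored
earlier without an event are excluded and counted — the convention that
reproduces the published table margins (318 cases / 17,129 controls).
Categorical NRI is the standard two-component sum; its CI is a percentile
bootstrap over individuals. The category-free NRI treats any risk increase
as upward movement and estimates event probabilities within movement groups
by KM at the horizon (the `nricens`-style estimator); its CI is normal with
the bootstrap SE, matching the "bootstrap standard errors" description.
With complete follow-up it reduces exactly to the classical binary formula
(tested). IDI weights each subject's case status by the KM-conditional
probability of being a case by the horizon (1 for observed cases, 0 for
those followed past it, 1 − S(t0)/S(c) for censoring at c), which also
reduces exactly to the uncensored closed form. An inverse-probability-of-
censoring variant was considered and not implemented; KM weighting is the
default throughout.

One behaviour worth knowing: because the multiplication-factor update moves
every marker-positive subject up and every marker-negative subject down,
cfNRI after updating depends only on the movement partition — a binary
presence update and a count update that shares its positivity set give
identical cfNRI, while IDI and the categorical NRI do discriminate between
them. Also, when the marker HR is estimated on the same data used to
evaluate reclassification, cfNRI carries in-sample optimism under a null
marker (the refit chases noise); the pipeline's null test bounds this rather
than pretending it away.

## Descriptive tests and MR estimators

The two-proportion z uses the pooled variance; Cochran-Armitage uses equally
spaced scores (two categories reduce exactly to z²); the rank-sum test is
Mann-Whitney with normal approximation and tie correction; logistic
regression delegates to statsmodels with continuous covariates standardised
per SD so odds ratios read per SD. Age bands are 45–54, 55–64, 65–74, ≥75,
with <45 reported separately.

MR operates on per-variant summary statistics. Wald-ratio SEs use the
first-order delta method (outcome SE / |exposure beta|), the conventional
choice that ignores exposure-side uncertainty. IVW is the inverse-variance
weighted mean of ratios; the random-effects variant inflates the SE by
max(1, √(Q/(k−1))) (never deflating). MR-Egger regresses outcome on exposure
betas with a free intercept and weights 1/se_out², after orienting exposure
betas positive (the orientation convention is configurable in principle via
`oriented()`; this default matches common practice). The weighted median is
the interpolated weighted median of ratios with a parametric-bootstrap SE.
Instruments are assumed independent — LD clumping is upstream of this
package. All estimators are invariant to per-variant sign flips (tested).

## Problem sizes and seeds

Parameter-recovery experiments use n = 200,000 (≈4,300 events), where the
3-SE band around the generating hazard ratios is ±9% (presence) and ±13%
(2+ level). The GND type-I simulation uses 500 replicates of n = 8,000 with
≥100 events per decile so the asymptotic reference applies. Bootstrap
defaults are 1,000 resamples in analysis drivers and smaller in unit tests.
Every stochastic routine takes an explicit seed; the pipeline fans a single
seed into per-stage child seeds via `numpy.random.SeedSequence.spawn`, so
stages rerun standalone reproduce the pipeline's artifacts byte-for-byte.

## Known limitations

- Synthetic covariates are mutually independent; joint-distribution effects
  (e.g. confounding strength) are weaker than in real cohorts.
- A single administrative censoring stream; no competing risks, no staggered
  entry, no covariate drift between risk assessment and imaging.
- The ICI smoother and the GND grouping are one concrete choice each among
  several in circulation; results at the third decimal can differ across
  implementations.
- Detection fixtures jitter rectangles; they exercise the metrics, not image
  realism.
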