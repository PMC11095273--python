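# Methods

## Scoring model

The CatLet score is additive over lesions: each lesion contributes the
myocardial-supply weight of its coronary segment times a stenosis
multiplier (2.0 non-occlusive, 5.0 occlusive; their ratio of 2.5 is the
penalty for total occlusion). The weight depends on the patient's
coronary circulation pattern, one of 54 classes formed by LAD length
(short/average/long) × diagonal size (small/intermediate/large) ×
dominance (six right-coronary variants including PDA-only and PDA-zero).
Only lesions with ≥50% diameter stenosis in vessels >1.5 mm are scored;
adverse lesion descriptors (calcification, length >20 mm, bifurcation,
tortuosity, thrombus burden, …) are recorded but never scored.

Two scoring conventions exist for occlusions. The default,
`force_non_occlusive`, scores every lesion with multiplier 2 — the
convention for registries in which occlusions are wired or ballooned open
far enough to grade the underlying stenosis; `as_recorded` honours the
occlusive flag. We apply the non-occlusive convention uniformly rather
than only to successfully reopened lesions, because per-lesion reopening
status is not part of the data model; the `as_recorded` mode covers the
other extreme.

ACEF I is `age/LVEF + 1{creatinine ≥ 2 mg/dL}`. The renal threshold is
inclusive, and creatinine reported in µmol/L is converted at 88.4 µmol/L
per mg/dL, so 176.8 µmol/L exactly earns the point. The Clinical CatLet
score is the product CS × ACEF.

### Segment weights

Published CatLet weights are proprietary, so weight tables are external
configuration validated on load (all 54 patterns present, positive
weights, per-pattern sums equal to the declared normalization constant to
1e-9). The shipped `illustrative_weight_table` is synthetic: 17 units of
myocardial territory (the 17-segment left-ventricular model) are
partitioned over terminal branches according to the pattern — the apex
share follows LAD length, the diagonal share follows diagonal size, and
the posterior territory splits between RCA and circumflex by dominance —
then each segment's weight is the territory downstream of it (flow
conservation: a proximal segment carries everything distal), and each
pattern is rescaled to a common normalization of 40. This yields
realistic relativities (left main ≈ 9.7, proximal LAD ≈ 4.5, distal
branches ≈ 0.5–1) and a plausible achievable score range (≈1 to ≈80), but
it is *not* the published weighting; every downstream statistic is
parameterized by whichever table is active, and no test depends on the
default's specific values.

## Survival analysis

Tertiles use left-open right-closed intervals (`score ≤ b1` low,
`b1 < score ≤ b2` mid, else top) with empirical 1/3–2/3 quantile bounds by
default and explicit bounds (e.g. CS 12/18) accepted. Kaplan–Meier,
log-rank and Cox models are delegated to lifelines; Cox ties use the Efron
approximation. Per-SD hazard ratios standardise the score by its cohort SD
(overridable), so doubling the SD halves the log-HR exactly. The trend in
event rates across ordered tertiles is tested with the Cochran–Armitage
score test with scores (1, 2, 3) — a proportions-based test chosen as the
standard equivalent of proprietary trend procedures; a survival-based
trend test would differ only when censoring is heavy and differential.
Adjusted models default to two covariate lists: the CS list (age, sex,
hypertension, diabetes, prior stroke, smoking, creatinine, LVEF, heavy
calcification) and the CCS list, which drops age, creatinine and LVEF
because they already enter the score through ACEF. Missing covariates are
a hard error; multiple imputation is out of scope.

## Risk models, discrimination, calibration

Predicted risks come from a univariable logistic model of the 4-year
binary outcome on the score. The binary label is defined at the
administrative horizon: patients censored event-free before 4 years have
unknown status and are excluded with a logged count (a sensitivity flag
treats them as non-events). A Cox-derived 4-year risk would be the main
alternative; the logistic choice matches the binary-outcome machinery
(Hosmer–Lemeshow, NRI) applied downstream and is a documented divergence
risk when comparing against survival-model-based reports.

AUC is the Mann–Whitney rank statistic with half-credit for ties;
variances and the paired two-model test use DeLong's structural
components (midrank implementation). Cross-validated AUC uses stratified
k-fold (default 10, seeded), refits the risk model per training fold, and
computes a single AUC with a DeLong CI on the pooled out-of-fold
predictions — stabler than averaging fold AUCs when events are rare.
Folds are reduced with a warning if either class has fewer members than
folds.

Calibration-in-the-large is the intercept of a logistic recalibration
with the predicted logit as offset (negative = overestimation); the slope
is the coefficient on the predicted logit. On training data these are 0
and 1 up to solver tolerance by the logistic score equations — a test
exploits this. Hosmer–Lemeshow groups patients into deciles of predicted
risk (quantile bins merged under ties) and refers the statistic to
chi-square with g−2 degrees of freedom, the fitted-model variant; the
external-validation variant (df = g) is not used. Predictions exactly at
0 or 1 are clipped to 1e-9 with a warning before the logit transform.
Lowess curves (fraction 2/3, 3 robustifying iterations) are
presentational only.

## Reclassification

Risk categories derive from the event rate: cutoffs at half, one and two
times the rate (requiring rate < 0.5), or explicit thresholds for
reproducing rounded published cutoffs such as {0.10, 0.20, 0.40} — the
exact rule applied to a 23.0% rate gives {0.115, 0.23, 0.46}, so the
rounded and exact variants are both exposed and the pipeline defaults to
the exact rule. Categorization is left-open right-closed (a prediction at
a cutoff falls in the lower category).

Category NRI nets upward and downward moves within events and non-events;
category-free NRI replaces category moves with any risk change, ties
counting as zero; IDI is the difference in discrimination slopes, computed
both as the mean-difference formula and via slopes (the two routes must
agree to 1e-12 in tests). Z statistics default to the Pencina (2008)
asymptotic SE including the −(net)²/n³ correction terms; the uncorrected
variant is exposed as `variance="simple"` because published analyses use
both, and the two differ by a few percent on realistic tables. NRI Z
values are therefore validated for sign and magnitude, not digit
equality. Confidence intervals by bootstrap and survival-NRI at a horizon
are out of scope.

## Synthetic cohort generator

The generator emulates a 1018-patient AMI registry followed 4 years:

* **CatLet score**: shifted log-normal, minimum 2, with µ = ln 12 and
  σ ≈ 0.641 fitted to the printed median 14 and IQR (10, 21). The fit
  matches median and quartiles; the implied SD (≈9.5–11 in samples) runs
  above the printed 8.1 because a two-parameter log-normal cannot match
  median, IQR and SD simultaneously — median/IQR were preferred as the
  more robust right-skew summaries.
* **Anatomy**: the three pattern axes are sampled independently at the
  printed marginal frequencies (joint dependence is unreported).
* **Lesions**: segments are chosen greedily against the sampled target
  score — repeatedly take the largest-weight segment whose non-occlusive
  score fits the remaining gap, recurring segments (serial lesions) only
  when the target exceeds the single-pass ceiling — so the recorded
  lesions score back *exactly* to the cohort's score under the active
  table, and round-trip tests are exact. A by-product is a mean of ≈2.2
  lesions/patient, above the printed 1.70 ± 0.94: matching both the score
  distribution and the lesion count would require the true weights.
  Occlusive flags (25%) and stenosis/diameter values are decorative for
  scoring under the default convention but exercise the `as_recorded`
  path.
* **Clinical components**: age ~ N(66, 11²), LVEF ~ N(53, 10²) (clipped),
  creatinine log-normal with median 71 µmol/L and σ = 0.23, all tied to
  the score's latent through a shared Gaussian frailty factor with
  loading 0.3 — a free parameter, not an estimate, as the registry's
  joint distribution is unreported. The resulting Clinical CatLet score
  lands on the printed median (≈17.7).
* **Outcomes**: per endpoint, exponential proportional hazards with a
  linear effect of the standardized score at the printed per-SD hazard
  ratio; the baseline rate is solved by root-finding so the expected
  4-year cumulative incidence equals the printed event count. Censoring
  is administrative at 4 years plus optional uniform dropout (default
  none). Endpoints are drawn independently, so the MACE composite is not
  forced to contain its components — a known simplification. The
  `hazard_score` switch ("cs" default, "ccs") selects which achieved
  score drives the hazards; under the default, CCS adds only noise, so
  synthetic CS-vs-CCS comparisons are expected to favour CS, opposite to
  the published registry. Patient-level registry results (AUCs 0.72/0.75,
  the printed NRIs and Z values) are therefore generator targets and
  report templates only, never numeric assertions.

The paired-prediction generator is a nested binormal model: outcome
Bernoulli(0.23); a shared and an added unit-variance Gaussian signal with
separations δ₁, δ₂ chosen so the closed-form AUCs Φ(δ/√2) equal 0.72 and
0.75. Predictions are exact Bayes posteriors, hence calibrated by
construction, which makes the model a clean oracle for AUC, NRI/IDI sign
and calibration tests.

All randomness in a generator call flows from one `numpy` `default_rng`
seed; a fixed config is byte-identical across calls.

## Problem sizes and numerical choices

Unit tests run at n between 40 and 4,000; distribution checks at
n = 10,000–50,000; hazard-ratio recovery uses 200 replicate cohorts at
n = 1,018 (95% CI coverage ≥ 90% observed ≈ 94–96%); the Hosmer–Lemeshow
null uses 500 fitted-model replicates at n = 1,000 with a KS test against
uniformity. These sizes keep the full suite under a minute apart from the
recovery block (≈30 s) while leaving Monte-Carlo error well inside the
asserted tolerances. Cox fits retry once with a damped Newton step
(step_size 0.25) before failing; baseline-hazard calibration uses Brent
root-finding on the log rate with xtol 1e-12; event times are floored at
1e-6 years to guard survival fitters against exact zeros.

## Known limitations

The illustrative weight table is a stand-in, not the published weighting;
absolute synthetic scores are only as meaningful as its relativities.
Endpoint draws are independent across endpoints; no competing risks,
time-varying effects or frailty terms. No missing data are generated
(the registry's missingness was handled by multiple imputation, out of
scope here). The category-NRI Z matches published values only up to the
variance-variant choice. Passing tests demonstrate correctness of the
machinery and recoverability under the generator's assumptions — not
reproduction of the registry's patient-level findings, which would
require the undeposited data.
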