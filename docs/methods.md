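# Methods

This note documents the generating model behind the synthetic cohort, the
training protocol, the evaluation conventions, and the design choices made
where more than one reasonable option existed.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort model

The generator emulates a pooled multi-source cohort of adults with stage 1–4
CKD (baseline eGFR 15–120 ml/min/1.73 m²), 40% Black and 60% White by design,
with the published summary characteristics as marginal targets.

**Covariates.**  Fifteen latent variables per patient (labs, blood pressures,
lipids, hemoglobin and three comorbidity liabilities) are drawn from a single
multivariate standard normal with a fixed positive-semidefinite correlation
matrix (checked at configuration time), then mapped to clinical scale:

- location/scale for roughly symmetric quantities (age, SBP/DBP, HbA1c,
  glucose, lipids, hemoglobin), with light physiologic floors;
- exponentiation for the right-skewed serum creatinine and UACR, so the
  configured "mean" is a clinical-scale **median** and the "sd" a log-scale
  SD (UACR medians 120 / 60 mg/g);
- quantile thresholding of the comorbidity liabilities at the configured
  prevalences (diabetes 45% / 40%; hypertension 75% / 70% and CVD 22% / 18%
  are configurable assumptions — no published values were available).

Baseline eGFR is *derived*, not drawn: it is the race-free CKD-EPI 2021
equation applied to the generated creatinine (women's creatinine is shifted
by a factor 0.79 so the eGFR distribution is sex-balanced).  Patients
falling outside the stage 1–4 window have creatinine pulled to the value
that puts eGFR exactly on the boundary, preserving eGFR ≡ CKD-EPI(scr)
everywhere.  Creatinine medians (1.82 / 1.70 mg/dL Black/White) were set
once so cohort mean eGFR lands near 45 / 48 ml/min/1.73 m².

**Outcome.**  Five-year progression is logistic on the latent scale:

    logit P(progression) = b_race + beta_race' z + gamma u

with race-specific coefficient vectors `beta_race`, a race-neutral
*unmeasured* frailty `u ~ N(0,1)` (weight `gamma` = 0.6 logits, representing
tubular-injury/inflammation burden and other risk the clinical features
cannot see), and the intercept `b_race` solved by bisection at generation
time so the marginal rate over the realized sample equals the configured
target (28% Black / 20% White) to 1e-3.  The per-race coefficient vectors
differ — the Black stratum weights albuminuria and systolic pressure more,
the White stratum glycemia and age more — which is what makes a race-blind
model group-miscalibrated.  Their overall scale (0.93) was fixed once so the
default pooled pipeline lands near out-of-fold AUC 0.79.

A note on the size of the pooled model's group bias: once the UACR, eGFR and
diabetes marginals are pinned at their published gaps, those covariate shifts
already explain most of the 28%-vs-20% outcome gap.  The residual race
effect — which is what a pooled model cannot represent and what drives its
per-group calibration-in-the-large — is therefore structurally bounded at
roughly −1.5 pp for Black patients under the defaults (sign and mechanism as
reported for real cohorts, magnitude smaller).  Pushing it further would
require either exaggerating the printed covariate gaps or weakening the
within-group predictiveness of albuminuria, both of which seemed worse
trade-offs.

**Biomarkers.**  TNFR1/TNFR2/KIM-1 are generated for a designated sub-cohort
of 1,200 patients (source label `EHR_A_like`) as log-normals whose log-scale
latent loads 0.8 on the frailty `u`, 0.35 on the standardized observable
risk score, remainder independent noise.  Because they carry signal the
clinical features lack, the 18-feature variant gains discrimination on the
subset (measured, not asserted as a constant, by the test suite).
Biomarkers are never imputed; the biomarker variant refuses rows without
measurements.

**Trajectories.**  The outcome label is generated first and the eGFR
trajectory second.  Six annual values follow a linear slope plus N(0, 1.5)
measurement noise — slopes N(−7, 1.5) for progressors, N(−1, 1) for
non-progressors, floored at 0 — redrawn (up to 50 times, then replaced by a
deterministic noise-free shape) until the composite endpoint rule re-derives
the assigned label, so the label/trajectory round-trip is exact by
construction.  Progressors additionally face a constant 0.08/year
kidney-failure hazard.  The composite rule reads: (a) some year reaches
≤ 60% of baseline *and stays there through year 5* ("sustained"), or (b) a
decline ≥ 5 ml/min/1.73 m² occurs in *two consecutive* year-intervals
("confirmed" = repeated), or (c) a kidney-failure event occurs in years 1–5.
The sustained-through-year-5 and two-consecutive-intervals readings are this
package's operationalizations of the qualitative words; both are documented
choices, configurable only by editing the rule.

**What the generator does not emulate.**  No attempt is made to match real
NHANES/CRIC/UK Biobank microdata beyond the printed summaries: no survey
weights, no informative missingness (clinical covariates are complete; only
biomarkers are structurally missing), no death as a competing risk, no
longitudinal covariates other than eGFR, and "Other" race categories are
supported by the data model but excluded from the default generator.  Tests
passing on this cohort therefore demonstrate correctness of the pipeline and
reproduction of the configured population structure — not validity on any
real population.

## Preprocessing

Order: winsorize raw labs to fixed physiologic bounds (e.g. creatinine
0.2–15 mg/dL, SBP 70–250 mmHg) → recompute eGFR from winsorized creatinine
via CKD-EPI 2021 (coefficients 142, κ = 0.7/0.9, α = −0.241/−0.302, exponent
−1.200, 0.9938^age, ×1.012 for women, stored in `EgfrParams` rather than
hard-coded) → natural-log UACR (and biomarkers) → mean-impute continuous
features → center/scale.  Imputation, centering and scaling statistics are
computed per (source cohort × training fold) and are a pure function of the
training rows; missing comorbidities are coded absent; binary indicators
pass through unscaled.  The 15-feature list is age, sex, baseline eGFR,
log-UACR, SBP, DBP, diabetes, hypertension, CVD, HbA1c, glucose, LDL, HDL,
triglycerides, hemoglobin — total cholesterol stays in the data model but
out of the feature set (nearly collinear with the lipid panel), and race is
never a feature.

## Models and training

Both strategies use the same architecture: input → 64 ReLU → 32 ReLU → 1
sigmoid, binary cross-entropy with positive-class weight 3, L2 penalty 1e-3,
Adam (lr 1e-3, β = 0.9/0.999, ε = 1e-8), mini-batches of 32, at most 100
epochs with early stopping (patience 10) on the weighted validation loss of
a stratified 20% slice of the training portion, best weights restored.
Minority-class rows in the remaining 80% are duplicated once (oversampling
factor 2); the validation slice and test folds are never oversampled.
Cross-validation is 5-fold, stratified jointly on (outcome × race), so every
fold carries comparable race composition and event rate.  All randomness
flows from one seed (default 42); training is bit-reproducible on a single
thread (with multi-threaded BLAS, agreement is to float round-off).

**Prior correction.**  The weighted loss (effective positive-class weight =
class weight × duplication factor = 6) deliberately inflates the raw sigmoid
outputs.  To report risks on the natural five-year probability scale, each
fitted model carries one logit shift, solved on its own training portion so
the mean corrected prediction equals that portion's event rate
(recalibration-in-the-large; for a fully converged well-specified logistic
model this shift equals ln 6).  The shift uses training rows only — nothing
from a test fold — and is global per model, so it cannot manufacture
*group*-level calibration: the pooled model keeps its per-race bias, and the
modular models' near-zero per-group calibration-in-the-large is a property
of per-race training, not of the correction.

The hybrid "shared network with race-specific final layer" variant is not
implemented (the strategy enum leaves room for it); fully separate per-race
models are the modular strategy.

## Evaluation conventions

- All metrics use out-of-fold predictions only; the evaluator rejects inputs
  with duplicated patient ids.
- Flagging is boundary-inclusive (risk ≥ threshold) everywhere, including
  decision curves.  The primary operating threshold is 30% five-year risk.
- AUC is the midrank Mann–Whitney statistic (ties ½); AUC confidence
  intervals and two-group difference tests use the DeLong structural-
  components variance, with disjoint groups treated as independent.
- Calibration-in-the-large, slope and ECE are computed within each CV fold
  and averaged (slope CI then from the between-fold spread); reliability
  deciles and the Brier score are computed on the pooled out-of-fold set,
  with equal-frequency bins and stable (score, id) tie-breaking.  The
  recalibration slope is maximum-likelihood logistic (IRLS, tolerance 1e-8).
- PPV with zero flagged patients is reported as an explicit undefined
  marker, never silently 0.
- Chi-square tests are Pearson, df = 1, no continuity correction; no
  multiple-testing correction is applied anywhere.
- The decision-curve grid is 5%–50% in 1% steps, computed on the combined
  cohort per strategy (per-race curves available via `threshold_sweep`).

## Numerical choices and degenerate inputs

Intercept calibration brackets the root in ±20 logits and raises if the
target is unreachable there; constant scores make the calibration slope
unidentifiable (error); single-class labels cannot be trained or scored
(error); a race stratum absent from a training fold is an error rather than
silently scored by another group's model; NaN losses abort training with
diagnostics rather than being masked.  Constant features are centered but
left unscaled.  Model weights serialize to a plain JSON format (shapes +
row-major values) and reload to bit-identical predictions.

## Problem sizes

Defaults were chosen so the whole default experiment is interactive: the
n = 7,500 cohort generates in about a second, each strategy trains its
5-fold complement of networks in a few seconds on one CPU, and the full
acceptance script completes in well under a minute.  Property tests that
need large samples (e.g. calibration-slope recovery) use n = 20,000 draws;
the modular-equals-pooled-under-homogeneity check runs at n = 3,000 because
per-race networks need enough rows for the finite-sample gap to shrink below
the assertion margin.

## Known limitations

- The cohort is synthetic; headline numbers characterize the generator plus
  pipeline, not any real population (see the generator caveats above).
- The modular strategy requires adequate per-group sample sizes; with small
  strata its networks underperform the pooled model (visible in the
  homogeneity test at small n).
- Only Black/White strata are generated by default; the data model admits
  "Other" but no default mechanism is provided.
- Fairness *mitigation* (per-group thresholds, reweighting, adversarial
  debiasing, equalized-odds post-processing) is deliberately out of scope:
  the package audits models, it does not repair them.
- Exact bitwise reproducibility of training requires a fixed thread count;
  across BLAS configurations results agree to float round-off only.
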