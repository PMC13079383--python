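# Methods

This note documents the models, conventions and numerical choices behind
`aupheno`, in the spirit of a statistical package's methods appendix.

## Quality control conventions

* A **valid frame** has tracking confidence ≥ 0.80 *and* success flag 1.
  The confidence cut is the protocol's "<80 % removed" rule read with a
  strict inequality (keep exactly 0.80); the success conjunction is our
  addition — a failed face fit yields meaningless AU values even at
  nominal confidence.
* A participant is **included** when valid_fraction ≥ 0.90 (again the
  strict reading of "<90 % excluded": exactly 90 % is kept). The
  denominator is the number of frames as recorded, not task duration.
* Confidence is stored as a fraction in [0, 1]; percent-style inputs
  (values > 1) are normalized on read. Rows with `face_id != 0` are
  dropped with a warning; multi-face disambiguation is out of scope.
* Head-pose nuisance screening reports pooled-frame Pearson r between
  each pose axis and every AU channel; zero-variance channels are
  reported as *undefined* (NaN), never as r = 0. |r| > 0.2 is flagged
  as non-negligible by default.

## Feature definitions

All features are duration-independent (proportions or per-frame
moments), because recording lengths vary:

* presence_mean / presence_sd — mean and **population** (1/N) SD of the
  binary `_c` channel. A convention had to be fixed; features are
  comparative inputs to a classifier, not inferential estimates, so the
  population SD is used.
* intensity_mean / intensity_sd — likewise for the 0–5 `_r` channel.
* presence_gt1 (the headline *Presence* metric) — proportion of valid
  frames with intensity **strictly** greater than 1.
* variation — flips of the presence channel between consecutive
  *retained* frames divided by the number of valid frames N (so the
  value lies in [0, 1 − 1/N]). Flips across a gap left by removed
  frames count as one comparison between the surviving neighbours: the
  denominator is the literal "sequence length", and gap handling must
  be fixed somehow; this keeps the statistic well defined after
  filtering.
* The binary `_c` channel feeds mean/SD and Variation; the headline
  Presence metric is the intensity>1 proportion. Both readings of
  "presence" are implemented because the two definitions circulate;
  the defaults follow the explicit metric definitions.
* **AU28** (lip suck) has no intensity regressor in the OpenFace
  dialect. Its classifier columns are presence_mean, presence_sd,
  variation, and an `activity` column (presence-channel mean) standing
  in for the intensity>1 proportion — keeping the classifier's
  information. Correlation analyses skip AU28 intensity entirely,
  giving the 53-test primary family (3 metrics × 18 AUs − 1).

Duplicating every frame leaves the proportion/mean features unchanged
and exactly halves variation (flip count preserved, denominator
doubled); this is covered by a regression test.

## Synthetic cohort generator

The generator emulates the study design the pipeline expects: 108 UHR
cases / 65 healthy controls, 45 ± 3 s recordings at 30 fps (all
configurable), ~35 % of cases antipsychotic(AP)-exposed, and a 10 %
contamination fraction of participants carrying a contiguous
low-confidence tracking span (12–35 % of frames).

**Per-AU on/off process.** Each AU evolves independently as a two-state
Markov chain with per-frame switching probabilities (p_on, p_off). The
presence channel is the current state. Intensity is drawn from the
state-conditional distribution: inactive = 5·Beta(1.2, 12) (mass near
0, exceedance of the >1 threshold ≈ 0.1), active = 1 + 4·Beta(a, b)
(bounded on [1, 5], mode > 1). Placing the active support above 1 —
rather than on [0, 5] — makes P(intensity > 1 | active) = 1, so the
three latent metrics invert in closed form:

* occupancy π from the presence metric: π = (m_p − e_in)/(1 − e_in),
  with e_in the inactive exceedance;
* active Beta mean (at fixed concentration) from the intensity metric;
* (p_on, p_off) from the flip-rate target s at fixed π via
  q = s / (2π(1 − π)), p_on = qπ, p_off = q(1 − π), using the
  stationary flip rate s = 2·p_on·p_off/(p_on + p_off).

This was a deliberate design choice: with a fixed-concentration Beta on
[0, 5] the presence-metric and intensity targets conflict (a planted
+0.15 presence shift realized as only ≈ +0.10), whereas the [1, 5]
support makes planted additive shifts on any latent metric realize
exactly (verified to ±0.03 by Monte-Carlo at n = 2 × 600).

**Heterogeneity and planted effects.** Per participant, each AU's
latent metric triple is baseline + Gaussian heterogeneity (SDs 0.06 /
0.25 / 0.02 for presence / intensity / variation) + additive group
shifts + AP-exposure shifts, clipped to feasible ranges; the *implied*
latents after clipping are recorded as `true_metrics`, so ground truth
stays honest at boundaries. Default planted effects mirror the
qualitative group findings the pipeline is meant to detect — cases:
AU7 presence +0.15, AU45 (blink) variation −0.05; AP-exposed cases:
suppressed presence/intensity/variation on AU5, AU15, AU23, AU26. The
*magnitudes* are simulation parameters chosen once for a clearly
detectable signal at desk-scale n; they are not estimates of the real
effect sizes, which the source data do not identify.

**Clinician ratings.** Outcomes (facial-affect Likert item, social-
skill factors/total, symptom composites) are linear-plus-noise
functions of the true metrics: a weighted metric composite is
standardized, mixed with independent noise to hit a target Pearson r,
then mapped to each outcome's group-specific mean/SD. The target is
interpreted as the *pooled-cohort* correlation, so for outcomes with a
group offset the within-construction correlation is inflated by the
analytically computed between-group variance attenuation. The target
refers to the correlation with the weighted composite (a positive
weight with a negative target plants a negative link). The 1–5 Likert
item discretizes a latent Gaussian at equispaced cut points
(half-integer thresholds), which preserves rank correlation with the
latent at mild attenuation. Symptom scores couple within cases only;
controls receive independent noise on their own scale, and controls
carry no SANS.

**Seed policy.** A master seed spawns one named child stream per
participant (keyed by the participant id), so cohorts sharing an id
prefix reproduce identically when the cohort grows; permutations, fold
shuffles and forest randomness likewise draw from a named stream
registry derived from the master seed.

**What the generator does not model** — and hence what passing tests do
not show about real data: cross-AU covariance (AUs are independent
chains; real AUs co-activate), rater behaviour beyond linear + noise,
non-stationary expressivity within a recording, camera/lighting
artifacts beyond a uniform low-confidence span, and any true effect
sizes. Recovery results on synthetic cohorts demonstrate that the
*pipeline* is correct and calibrated, not that real UHR/control data
are separable at any particular accuracy.

## Classifier protocol

* Stratified folds come from scikit-learn's `StratifiedKFold`
  (shuffled, seeded); per-fold class counts are within 1 of exact
  proportionality.
* Feature selection: per-feature Welch two-sample test on outer-training
  rows, keep p < 0.05 (configurable). Constant features have an
  undefined statistic and are never selected. An empty selection falls
  back to all features (`fallback_used` recorded) — with informative
  labels this essentially never happens; under permuted labels it does.
* Inner loop: grid search by mean inner AUC; ties keep the first combo
  in the deterministic grid order. A single-point grid skips the inner
  loop (the refit is unchanged). The winner is refit on the full outer
  training set and evaluated once on the held-out fold.
* Metrics (accuracy, AUC, sensitivity, specificity, F1) treat *case* as
  the positive class. Means and SDs aggregate over all outer folds ×
  repeats (sample SD, ddof = 1). Class weighting is off by default and
  exposed as a config option.
* Permutation test: one permutation of the label vector per replicate,
  applied *before* feature selection, the full procedure rerun;
  p = (b + 1)/(B + 1) for mean AUC and mean accuracy separately, so
  p ≥ 1/(B + 1) always. By default the null wraps the full repeated
  procedure; a config switch (`permute_full_repeats=False`) wraps a
  single repetition instead.
* Default grids are intentionally small (forest: trees/depth/features
  per split; SVM: kernel and cost over a standardized pipeline) for
  desk-scale runtime; no grid is claimed to match the original study's
  (unreported) grid.

## Multiple-testing and validation conventions

* BH step-up is implemented directly (sorted p·m/rank with enforced
  monotonicity) and cross-checked in tests against
  `statsmodels.multipletests` as an independent oracle.
* Each correction runs strictly within its declared family: the
  53-test primary family; one family per exploratory outcome (the
  conservative reading of per-matrix presentation); the group-test
  family over the 106 classifier features. Family sizes are recorded on
  every result table (`attrs["family_size"]`).
* Pearson p-values use the exact t transform with n − 2 df; pairwise
  complete cases; two-sided everywhere. The Likert facial-affect item
  is treated as continuous for Pearson, as is conventional.
* Group tests are Welch (unequal variance) t-tests — group sizes are
  unequal by design. Covariate adjustment refits each feature as
  OLS(feature ~ group + covariates) and reports the group-coefficient
  p.
* AP sensitivity: stage 1 compares AP-naive vs AP-exposed cases on all
  53 headline-metric variables (uncorrected gate at α = 0.05, matching
  its role as a sensitivity screen); stage 2 runs only for gated
  variables, each case subgroup vs controls.
* Reports label 0.001 ≤ p < 0.01 as "trend" purely for display.

## Problem sizes used by the test-suite and acceptance script

Chosen as desk-scale sizes with adequate statistical power:

* Null calibration: 200 null datasets (n = 40, 20 features) at 49
  permutations with a linear-SVM single-point grid and one repeat.
* Planted-effect recovery: one cohort of 60/40 at the default 45 s /
  30 fps, random forest with a 2-point grid (50 trees), one repeat,
  100 permutations.
* Coupling recovery: 100 cohorts of 108/65 at 20 s (shorter sequences
  only *increase* measurement attenuation, making the check harder, so
  the target tolerance remains meaningful).
* Leakage guard: every fold of a 5 × 5 × 2 design with a 2-point SVM
  grid, asserting identical selections and identical fold-model
  decision values after flipping the held-out labels.
* End-to-end determinism: two full pipeline runs on an 8/6 cohort at
  6 s, compared by per-file SHA-256.

## Known limitations

* The chain-solve clips infeasible latent targets (e.g. presence below
  the inactive exceedance floor ≈ 0.1); `true_metrics` records the
  clipped values, but extreme configured shifts will not realize fully.
* Realized metrics attenuate toward their latents with shorter
  recordings; couplings are calibrated on the latent scale, so very
  short sequences under-recover target correlations.
* Sensitivity/specificity are undefined (NaN) for a fold whose test
  split lacks a class — prevented by the stratification preconditions,
  but possible with hand-built fold plans.
* The report's heatmaps annotate r only where q < 0.05; an empty
  annotation set is a legitimate outcome on null data.
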