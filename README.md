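# aupheno

Automated facial **action-unit (AU) expressivity analysis** for
psychosis-risk research.

Blunted facial affect is a clinically meaningful but hard-to-quantify
feature of the psychosis spectrum. Individuals at ultra-high risk (UHR)
for psychosis show only *subtle* expressivity differences from healthy
controls, which clinician ratings can miss. `aupheno` implements a
complete, testable pipeline for quantifying facial expressivity from
OpenFace 2.0 per-frame AU streams recorded during brief (~45 s) video
tasks, and for validating those quantities against clinician ratings:

1. **Ingest + QC** — parse OpenFace-dialect CSVs (18 AUs, intensity
   `AU**_r` on 0–5 and binary presence `AU**_c`); drop frames with
   tracking confidence < 80 % or a failed fit; exclude participants with
   < 90 % valid frames; check head-pose (pitch/yaw/roll) nuisance
   correlations with every AU channel.
2. **Duration-independent features** — per AU: mean and population SD of
   presence and of intensity, plus the three headline metrics

   - *Presence*  P(AU) = #{frames with intensity > 1} / #valid frames
   - *Intensity* I(AU) = mean intensity over valid frames
   - *Variation* V(AU) = #{active/inactive flips between consecutive
     frames} / #valid frames

   Six features per dual-channel AU (AU28 has no intensity channel),
   106 classifier columns in total.
3. **Classification** — case vs control with a random forest (or SVM)
   under **repeated nested stratified cross-validation** (5 outer × 5
   inner folds × 5 repeats by default). Feature selection (per-feature
   Welch test, keep p < 0.05, all-features fallback) runs strictly on
   outer-training rows; hyperparameters are tuned by mean inner AUC.
   Significance comes from a permutation test that relabels
   participants *before* feature selection and reruns the whole
   pipeline (add-one p = (b + 1)/(B + 1), B = 100 by default).
4. **Clinical validation** — Pearson correlations of the 3 metrics × 18
   AUs (53 tests; AU28 intensity undefined) with the clinician-rated
   facial-affect item, corrected by Benjamini–Hochberg FDR and by
   Bonferroni at 0.05/53 ≈ 0.000943; exploratory families per
   social-skill factor and symptom score; group Welch tests with
   optional covariate adjustment; and the two-stage antipsychotic
   (AP-naive vs AP-exposed) sensitivity analysis.

Because video-derived datasets of this kind are not publicly
depositable, the package ships a first-class **synthetic cohort
generator**: each AU evolves as a two-state Markov chain with
state-conditional intensities, participant-level heterogeneity, planted
group/medication effects, and clinician ratings coupled to the true
latent metrics at configurable correlation strengths. Every downstream
stage is tested against this generator's known ground truth.

## Worked example

```python
from aupheno import (CohortConfig, CVConfig, NestedCVClassifier,
                     ExpressivityValidation, generate_cohort,
                     filter_low_confidence, assess_validity,
                     build_feature_matrix)
from aupheno.simulate import clinical_frame

cohort = generate_cohort(CohortConfig(n_case=60, n_control=40, seed=42))
filtered, entries = zip(*(filter_low_confidence(p.sequence) for p in cohort))
qc = assess_validity(list(entries))
matrix = build_feature_matrix(list(filtered), qc,
                              {p.id: p.group for p in cohort})

clf = NestedCVClassifier(matrix, CVConfig(
    seed=42, n_repeats=2, model_family="random_forest",
    hyperparameter_grid={"n_estimators": [50], "max_depth": [None, 4]}))
results = clf.fit()
clf.permutation_test(results, n_permutations=25)
print(results.summary())
```

prints

```
Nested stratified cross-validation
==================================================
model family: random_forest
outer folds: 5  inner folds: 5  repeats: 2  (n folds = 10)
--------------------------------------------------
    accuracy: 0.871 (SD = 0.087)
         auc: 0.936 (SD = 0.064)
 sensitivity: 0.910 (SD = 0.110)
 specificity: 0.814 (SD = 0.166)
          f1: 0.892 (SD = 0.075)
--------------------------------------------------
permutation p (mean_auc): 0.0385  [B = 25]
permutation p (mean_accuracy): 0.0385  [B = 25]
--------------------------------------------------
top selected features (count / folds):
       AU07_intensity_sd: 10 / 10
       AU07_presence_gt1: 10 / 10
      AU07_presence_mean: 10 / 10
        AU07_presence_sd: 10 / 10
       AU23_presence_gt1: 10 / 10
```

Metrics are means ± SD over the outer folds; the permutation p is the
add-one tail probability of the observed mean AUC/accuracy under label
relabeling before feature selection (its floor here is 1/26). The
selection table shows which AU features the training folds kept — in
this cohort the planted AU7 effect dominates. Clinical validation:

```python
val = ExpressivityValidation(matrix, clinical_frame(cohort)).fit()
print(val.summary())
```

```
Clinical validation of AU metrics
==================================================
primary family: 53 Pearson tests vs hisoc_item1
Bonferroni per-test alpha: 0.000943
FDR-significant (q < 0.05): 2
Bonferroni-significant:     2
--------------------------------------------------
group Welch tests with q < 0.05: 8 of 106
AP sensitivity: 15 variable(s) passed stage 1
```

The same analysis is available from the shell:

```bash
aupheno run-all --simulate --out results_dir --seed 42 --model rf \
    --n-permutations 100 --frame-confidence 0.80 --valid-fraction 0.90
```

which writes the cohort, QC report, feature matrix, fold-level CV
results, permutation null, correlation tables, heatmap figures, a
markdown + JSON report, and a run manifest with per-file checksums
(re-running with the same seed reproduces identical checksums).

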