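# dsidx

Disease State Index (DSI) modelling of global cognitive decline in a
general population: a relevance-weighted hierarchical ensemble
classifier, the general-cognitive-factor (g-factor) outcome it predicts,
a calibrated synthetic cohort generator, and the repeated
cross-validation protocol used to evaluate it.

## The problem

Screening a non-demented, middle-aged-and-older population for people at
risk of *significant global cognitive decline* — the 5% whose general
cognitive ability falls fastest per year — from baseline data alone:
age, sex, education, APOE-ε4 carriership, cardiovascular risk factors,
gait factors, baseline cognition and a large catalogue of brain-MRI
measures. Population datasets are incomplete by nature, so the
classifier must tolerate missing values without imputation, and with
~5% positives it must be robust to class imbalance.

## The model

**Outcome.** The g-factor is the first unrotated principal component of
five cognitive tests (Stroop interference, letter-digit substitution,
verbal fluency, 15-word learning delayed recall, Purdue pegboard),
z-scored, oriented so higher g = better cognition. Decline per year is
Δg / follow-up time; the `floor(0.05 n)` steepest decliners are the
positive class.

**Classifier.** For each feature, an empirical *fitness* function maps a
value x to a class-membership score built from training counts at
cut-off x,

    f(x) = FN(x) / (FN(x) + (P/N)·FP(x)),

the P/N factor equalising the class sizes. Each feature's weight is its
*relevance* R = max(sensitivity + specificity − 1, 0) — the Youden index
of its own fitness classifier, clamped at zero. Scores are combined
through a category hierarchy by relevance-weighted averaging,

    DSI = Σᵢ Rᵢ fᵢ / Σᵢ Rᵢ ,

recursively up to a single index in [0, 1]; missing features are simply
skipped and the weights renormalised. DSI > 0.5 ⇒ positive call.

**Evaluation.** 500 repetitions of stratified 2-fold cross-validation
(both fold orders scored ⇒ 1000 AUC values), with 95% intervals from the
corrected resampled t-test (naive variance inflated by 1/(k·r) + n₂/n₁)
and a zero-in-CI rule for AUC differences; four age-handling variants
(age in/out × features age-corrected or not), cumulative feature sets,
relevance-threshold selection on the MRI features, and an extreme-DSI
(< 0.2 or > 0.8) subgroup analysis.

The original study's cohort is not public, so the package ships a
generator producing cohorts with the published structure (age
60.9 ± 9.1, 55.6% female, follow-up 5.7 ± 0.6 years, biomarker anchors
from the published baseline table, age-driven decline); see
`docs/methods.md` for the calibration and its limits.

## Worked example

```python
import dsidx
from dsidx.evaluation import ExperimentSpec, compare_aucs, run_experiment

cohort = dsidx.generate_cohort(dsidx.default_config(n_subjects=2542, seed=5))
gmodel = dsidx.fit_gfactor(cohort.baseline_tests())
labels = dsidx.label_decline(
    dsidx.score_gfactor(gmodel, cohort.baseline_tests()),
    dsidx.score_gfactor(gmodel, cohort.followup_tests()),
    cohort.data["followup_years"].to_numpy(),
    subject_id=cohort.data["subject_id"].to_numpy(),
)
age_only = run_experiment(cohort, labels,
                          ExperimentSpec(feature_set=["age"], n_repetitions=25, seed=1))
all_feat = run_experiment(cohort, labels,
                          ExperimentSpec(feature_set=["all"], n_repetitions=25, seed=1))
diff, ci, significant = compare_aucs(all_feat, age_only)
```

Running this (it is `examples/04_cross_validation.py`) prints:

```
age only      mean AUC 0.848 (95% CI 0.819-0.877, 50 splits)
all features  mean AUC 0.832 (95% CI 0.800-0.865, 50 splits)
difference -0.016 (95% CI -0.031 to -0.001) -> significant
```

Age alone is the dominant predictor on this synthetic cohort: the labels
are the tail of an age-dependent decline rate, and every other feature
carries age-derived signal plus noise, so stacking the full catalogue on
top of age does not help (here it even costs a little). The g-factor fit
behind those labels (`examples/02_gfactor_outcome.py`) reports a first
principal component explaining ≈ 51% of test variance and, at n = 2542,
exactly 127 decliners against 2415 stable subjects.

The other `examples/` scripts each demonstrate one capability: cohort
generation, DSI fitting/scoring with missing data, the MRI
relevance-selection sweep, and the subgroup/masking analyses. A thin CLI
covers the same pipeline from a shell:

```bash
dsidx generate --n 2542 --seed 1 --out cohort
dsidx label --in cohort --out labels.csv
dsidx evaluate --cohort cohort --labels labels.csv --features age --reps 100 \
    --seed 1 --out summary.json
dsidx pipeline --out run/ --seed 1 --reps 10
```

## Layout

```
src/dsidx/          synthetic, cohort, gfactor, preprocessing, dsi,
                    hierarchy, evaluation, pipeline, cli
src/dsidx/data/     default generator config and feature hierarchy (YAML)
examples/           one short narrative script per capability
tests/              unit, property and end-to-end acceptance tests
docs/methods.md     models, conventions, calibration, limitations
```
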