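# Methods

This note records the models implemented in `dsidx`, the conventions that
were genuinely open when building them, the calibration of the synthetic
cohort generator, and what the test suite's results do and do not say
about real data.

## The Disease State Index

The DSI is a supervised ensemble of univariate empirical classifiers
combined through a feature hierarchy.

**Fitness.** For a feature with positive-class training values (size *P*)
and negative-class values (size *N*), the fitness of a raw value *x* is

```
f(x) = FN(x) / (FN(x) + (P/N) · FP(x))
```

where, in *oriented* values (higher = more like the positive class),
FN(x) = #{positives ≤ x} and FP(x) = #{negatives > x}. The *P/N* factor
rescales the negative class to the positive class's size, so the score is
insensitive to class imbalance — important here, where positives are 5%
of the cohort. f is a step function in [0, 1]; values above 0.5 vote
positive.

Conventions the formula itself does not fix:

- *Tie side.* Ties sit with the "≤" (FN) side. Any consistent choice is
  defensible; this one makes f monotone non-decreasing, which is what
  lets a single-feature DSI preserve the feature's ranking.
- *Gaps.* In a gap between the two classes' supports both counts can be
  zero; the 0/0 is defined as 0.5 (maximally uninformative).
- *Orientation.* Chosen per feature as the sign of (Mann-Whitney AUC −
  0.5) on the raw training values, with the tie going to +1. A feature
  whose orientation is ambiguous has AUC ≈ 0.5 and earns relevance ≈ 0,
  so the tie rule is inert.
- *Unusable features.* A feature observed in only one class gets
  relevance 0 and constant fitness 0.5, and so vanishes from every
  composite.

**Relevance.** Each feature's weight is the Youden index of its own
fitness classifier evaluated on the training subjects, clamped at zero:

```
R = max(sensitivity + specificity − 1, 0)
```

with sensitivity = fraction of training positives with f > 0.5 and
specificity = fraction of training negatives with f ≤ 0.5. Because R is
computed on the same data the fitness was built from, it is an
optimistic, overfit-prone quantity — by design; see *Limitations*.

**Hierarchy.** At every node a subject's composite score is the
relevance-weighted mean of the observed children, `Σ R_i f_i / Σ R_i`.
Missing children are skipped and the weights renormalised, which is the
mechanism by which the index tolerates missing data without imputation.
The fitness/relevance construction is applied recursively: a node's
relevance is the clamped Youden index of its own composite training
scores against the 0.5 cut-off (composites already live on the fitness
scale, so no re-fitting of a fitness function is needed — this is the
natural reading of "repeat recursively", though others are conceivable).
The root composite is the DSI; a subject is called positive iff
DSI > 0.5 (exactly 0.5 is called negative; only strict exceedance is
defined as positive).

*Zero-relevance children carry no weight.* If no observed child of a node
has R > 0 the composite is missing rather than an unweighted mean. This
is the only convention under which (a) adding an R = 0 feature never
moves any score, (b) a subject's DSI with a feature missing equals the
DSI from a hierarchy without that feature, and (c) a node whose
descendants are all unusable is missing. The cost is that a hierarchy
consisting solely of R = 0 features scores nobody — acceptable, since
such a model has no information anyway.

*Exactness of the monotone-transform identity.* A single-feature DSI is a
monotone non-decreasing transform of the (oriented) feature, so it
preserves the feature's AUC except where the transform collapses a
positive-negative pair onto a common plateau. On the training sample this
can only happen on the f = 1 plateau (a negative above all other
negatives, with positives above it) or, for out-of-sample values, the
f = 0 plateau. When the sample extremes are negatives, no pos-neg pair is
collapsed and the identity is exact; the test suite constructs exactly
that case, and uses a 0.02 tolerance when scoring arbitrary held-out
halves.

## Outcome: the g-factor and the 5% tail

The general cognitive factor is the first unrotated principal component
of five cognitive tests (Stroop interference, letter-digit substitution,
verbal fluency, 15-word learning delayed recall, Purdue pegboard),
extracted from the correlation matrix because the tests have
incommensurate units. Loadings have unit norm; the sign is fixed so the
delayed-recall loading is positive (higher g = better cognition).
Subjects with any missing test are excluded listwise from the fit and
reported.

The baseline standardisation and loadings are reused to score the
follow-up visit — the only choice that makes the difference
`Δg = g_follow − g_base` a movement in a single metric. Annualised
decline is Δg divided by each subject's follow-up interval. The positive
class is the `floor(0.05 · n)` subjects with the most negative annual
change (at n = 2542 both floor and round give 127; floor is the
deterministic, conservative pick). Ties exactly at the cut are broken by
ascending subject id for reproducibility. The reported threshold is the
least negative annual delta among the positives.

## Age correction and MRI feature selection

Non-binary features are residualised on age by per-feature ordinary least
squares; binary features and age itself are untouched, and missing cells
stay missing. By default the correction is fitted on the whole dataset in
a single pass (mirroring the evaluated protocol; it leaks only label-free
information); a per-training-fold variant (`age_correction_scope="fold"`)
is provided for leakage-sensitive use. Ordinal categoricals (education
1–7, smoking 0/1/2) are treated as numeric non-binary features — the
rank-based fitness needs only an ordering.

MRI feature selection thresholds each MRI feature's *whole-dataset*
univariate relevance at t ∈ {0.00, 0.01, …, 0.10} and drops features
below t, deliberately before any CV split. This is optimistic (training
data participates in the selection) and is retained as a faithful
property of the protocol being reproduced: any AUC gain from selection is
an upper bound. If a threshold empties the MRI branch, the branch is
dropped with a warning — the index tolerates an absent branch — and a
sweep records an undefined row for an emptied feature set.

## Evaluation protocol

Repeated stratified 2-fold cross-validation: each repetition draws a
random half/half split preserving the class ratio (within each class the
folds differ by at most one subject), and both orientations of
(train, test) are scored, so r repetitions yield 2r AUC values — 1000 at
the default r = 500, matching the protocol's stated count. AUC is the
Mann-Whitney probability with ties counting one half.

The mean AUC's 95% interval uses the corrected resampled t-test
(Nadeau–Bengio): the sample variance s² of the k·r values is inflated to
`s²·(1/(k·r) + n₂/n₁)` with n₂/n₁ the test/train size ratio (1 for
2-fold), and the interval is `m ± t₀.₉₇₅,ₖᵣ₋₁·√(corrected variance)`.
Worked check: values {0.7, 0.8} give m = 0.75 and half-width
12.706·√0.0075 ≈ 1.1003. Two models are significantly different only if
the corrected interval of their per-split differences (on the identical
split sequence) excludes zero. On iid inputs the corrected interval
over-covers — a known conservative behaviour, asserted by simulation in
the tests.

Four age-handling variants: (1) age in, no correction; (2) age out, no
correction; (3) age in, non-binary features except age corrected;
(4) age out, corrected. Per-repetition relevance distributions are taken
from the trained hierarchy of each fold (two records per repetition,
pooled). Degenerate splits (possible only at toy scale) are dropped from
the aggregate with a logged count, never imputed.

The extreme-score subgroup analysis restricts held-out calls to subjects
with DSI < 0.2 or > 0.8 — refusing a diagnosis near the boundary — and
reports the subgroup AUC plus retention.

## Synthetic cohort generator: what it emulates, and its calibration

The generator is first-class, tested code that produces cohorts with the
statistical structure the analysis assumes. Anchors are the published
control-group values of the modelled population (a Dutch
population-based ageing cohort): age 60.9 ± 9.1 years truncated to
[45, 95] (the parent normal's parameters are solved so the *truncated*
distribution has the configured mean/SD), 55.6% female, follow-up
5.7 ± 0.6 years, and per-feature means/SDs/prevalences from the
published baseline table (e.g. hippocampus 6.8 ± 0.7 mL, global MD
0.7 ± 0.03 ×10⁻³ mm²/s). Skewed features reported as median/IQR
(white-matter-lesion volume, alcohol) are log-normal; dichotomous
features are Bernoulli with a logistic age effect; education and smoking
are rounded latent normals.

Structure:

- One latent ability G drives the five test scores with loadings ±0.612,
  chosen so the first principal component explains ≈ 50% of test
  variance, matching the magnitude reported for a real g-factor
  (qualitatively, not numerically). Time-scored tests load negatively.
- Each subject's annual g-change is `d = −0.02 − 0.005·(age − 60.9) +
  N(0, 0.07)` g-units/year. These three numbers were set once, from the
  published group summaries: they imply a positive-group age of ≈ 71
  vs ≈ 60 in controls, decline SDs of ≈ 0.07–0.08 g/year in the two
  groups, and a 5%-tail threshold of ≈ −0.16 to −0.21 g/year — all in
  the published ranges. Follow-up test scores are the baseline scores
  shifted by d through each test's loading.
- Biomarker age slopes are (positive − control mean difference) divided
  by the groups' ≈ 10.9-year age gap, so the published group contrasts
  arise through age alone. Age slopes for features without a published
  contrast (gait factors, flow) are plausible inventions recorded in the
  default config.
- Missingness is MCAR per feature (defaults: 3–10% on diffusion, flow
  and gait, emulating incomplete ascertainment); the structured
  680-subject block mask is produced only by `mask_subset_features`,
  keeping the base generator auditable.

What the generator deliberately does *not* emulate: inter-feature
correlation beyond the shared age and latent-G channels, non-linear age
effects, informative (MNAR) missingness, practice effects at retest, and
attrition. Consequently, passing tests show that the pipeline recovers
the structure it assumes, not that the published real-data AUC values are
reproduced — those depend on a non-public cohort and are out of scope.

## An observed property: residualising discrete features injects age

While validating the "no signal left" null (variant 4 on a cohort whose
only label signal is a linear age effect), one genuine mechanism
surfaced: OLS-residualising a *coarsely discretised* ordinal feature
(education with 7 levels, say) on age replaces each tied block by values
ordered by −age. The rank-based fitness then recovers an age ranking
within blocks, and an otherwise pure-noise feature yields real held-out
AUC (≈ 0.6 in our setting). The chance-level null is therefore only
well-posed for continuous features, and the corresponding test builds
its null cohort that way. The same applies to binary features in the
other direction: the protocol leaves them uncorrected, so a logistic age
effect in a binary feature survives variant 4 by construction. Users
age-correcting ordinal features should be aware the residual is not
age-free in rank terms.

## Problem sizes and numerical choices

Default experiment sizes in the tests and the acceptance script are a
package choice balancing stability against desk-scale runtimes: the
parameter-recovery experiment uses 100 repetitions (200 splits) at
n = 2542; the qualitative-ordering suite uses 10–25 repetitions; the
selection sweep uses the protocol's own reduced 10×2-fold size; the
Monte-Carlo age-AUC oracle uses 10⁶ simulated subjects (MC standard
error ≈ 0.001). All randomness flows from explicit seeds; one global
seed fans out to stage seeds via `SeedSequence` (recorded in the
pipeline manifest), and identical seeds reproduce every number exactly.

Numerical details: fitness counts use sorted arrays and binary search
(exact integer counts, no interpolation or smoothing of the step
function); relevance comparisons use strict `> 0.5` / `≤ 0.5` exactly as
defined; constant features are detected by zero range rather than a
floating-point SD; the corrected CI returns a zero-width interval on
constant input.

## Known limitations

- Relevance is an in-sample quantity; reported relevance distributions
  are optimistic, as is whole-dataset MRI selection (both faithful to
  the protocol reproduced here).
- The hierarchy below the top level is a plausible reconstruction from
  the published feature groupings; the original's full tree was not
  published. A different tree averages differently and changes the DSI.
- No probabilistic calibration of the DSI is attempted; 0.5 is a
  convention, not a calibrated risk threshold.
- The corrected resampled t-test is a heuristic variance correction; its
  intervals are conservative rather than exact.
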