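"""The cross-validation evaluation protocol.

Performance is estimated with repeated stratified 2-fold cross-validation:
each repetition draws a random half/half split preserving the class
ratio, and *both* orientations of (train, test) are scored, so ``r``
repetitions yield ``2r`` AUC values (1000 at the default r = 500). The
mean AUC's uncertainty is expressed with the corrected resampled t-test
for cross-validation estimators (Nadeau-Bengio): the naive variance of
the per-split values is inflated by ``1/(k*r) + n2/n1`` — the test/train
size ratio, 1 for 2-fold — to account for the overlap of training sets
across repetitions. Two models are declared significantly different only
when the corrected 95% CI of their per-split AUC differences excludes
zero.

Four age-handling variants of the model are supported:

1. age included, no age correction        (the default model)
2. age excluded, no age correction
3. age included, non-binary features age-corrected (except age)
4. age excluded, non-binary features age-corrected

plus cumulative feature-set expansion, a relevance-threshold selection
sweep over the MRI features, and the extreme-score subgroup analysis
(only subjects with DSI < 0.2 or > 0.8 are given a call).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from sklearn.metrics import roc_auc_score

from .cohort import CohortTable
from .dsi import fit_hierarchy, score_subjects
from .gfactor import OutcomeLabels
from .hierarchy import (
    HierarchySpec,
    default_hierarchy,
    hierarchy_features,
    prune_hierarchy,
    resolve_feature_set,
)
from .preprocessing import apply_age_correction, fit_age_correction, select_mri_features

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentSpec",
    "CVResult",
    "stratified_2fold_splits",
    "auc",
    "corrected_resampled_ci",
    "compare_aucs",
    "run_experiment",
    "cumulative_feature_sets",
    "selection_sweep",
    "extreme_subgroup_auc",
]


@dataclass
class ExperimentSpec:
    """Settings of one cross-validation experiment."""

    feature_set: list[str] = field(default_factory=lambda: ["all"])
    model_variant: int = 1
    n_repetitions: int = 500
    n_folds: int = 2  # protocol-fixed
    seed: int = 0
    mri_selection_threshold: float | None = None
    age_correction_scope: str = "full"  # or "fold"

    def __post_init__(self) -> None:
        if self.model_variant not in (1, 2, 3, 4):
            raise ValueError(f"model_variant must be 1..4, got {self.model_variant}")
        if self.n_folds != 2:
            raise ValueError("the protocol fixes n_folds = 2")
        if self.age_correction_scope not in ("full", "fold"):
            raise ValueError(f"unknown age_correction_scope {self.age_correction_scope!r}")


@dataclass
class CVResult:
    per_split_auc: np.ndarray  # k*r values (NaN for degenerate splits)
    mean_auc: float
    ci_low: float
    ci_high: float
    relevance_records: pd.DataFrame  # repetition, fold, category, relevance
    spec: ExperimentSpec | None = None
    n_excluded_splits: int = 0

    def summary(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_splits": int(len(self.per_split_auc)),
            "n_excluded_splits": self.n_excluded_splits,
        }


def stratified_2fold_splits(
    labels, n_repetitions: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified half/half partitions; both fold orders are emitted.

    Within each class the two folds differ in size by at most one. A class
    with fewer than 2 members cannot be stratified and is rejected.
    """
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    if len(idx_pos) < 2 or len(idx_neg) < 2:
        raise ValueError(
            f"need >= 2 members per class, got {len(idx_pos)} positives / "
            f"{len(idx_neg)} negatives"
        )
    splits = []
    for _ in range(n_repetitions):
        fold_a = []
        fold_b = []
        for idx in (idx_pos, idx_neg):
            perm = rng.permutation(idx)
            half = len(perm) // 2
            fold_a.append(perm[:half])
            fold_b.append(perm[half:])
        a = np.sort(np.concatenate(fold_a))
        b = np.sort(np.concatenate(fold_b))
        splits.append((a, b))
        splits.append((b, a))
    return splits


def auc(scores, labels) -> float:
    """Mann-Whitney AUC; ties count half. NaN scores are excluded pairwise."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    ok = ~np.isnan(s)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.debug("auc: dropping %d unscored subjects", n_dropped)
    s, y = s[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(y, s))


def corrected_resampled_ci(
    per_split_values,
    k_folds: int = 2,
    r_repetitions: int | None = None,
    level: float = 0.95,
    test_train_ratio: float = 1.0,
) -> tuple[float, float, float]:
    """Mean and corrected resampled t-test CI for repeated-CV estimates.

    The sample variance s^2 of the k*r per-split values is inflated to
    s^2 * (1/(k*r) + n2/n1) with n2/n1 the test/train size ratio (1 for
    2-fold); the CI is m +- t_{level, k*r-1} * sqrt(corrected variance).
    Constant input yields a zero-width interval.
    """
    v = np.asarray(per_split_values, dtype=float)
    v = v[~np.isnan(v)]
    kr = len(v)
    if kr < 2:
        raise ValueError("need at least 2 per-split values")
    if r_repetitions is not None and kr != k_folds * r_repetitions:
        raise ValueError(
            f"expected {k_folds * r_repetitions} values, got {kr}"
        )
    m = float(np.mean(v))
    s2 = float(np.var(v, ddof=1))
    corrected = s2 * (1.0 / kr + test_train_ratio)
    half = float(t_dist.ppf(0.5 + level / 2, kr - 1) * np.sqrt(corrected))
    return m, m - half, m + half


def compare_aucs(
    result_a: CVResult, result_b: CVResult, level: float = 0.95
) -> tuple[float, tuple[float, float], bool]:
    """Paired comparison of two CV results on the identical split sequence.

    Returns (mean difference a-b, CI, significant). Significance means the
    corrected CI of the per-split differences excludes zero.
    """
    if len(result_a.per_split_auc) != len(result_b.per_split_auc):
        raise ValueError("results have different numbers of splits")
    if (
        result_a.spec is not None
        and result_b.spec is not None
        and result_a.spec.seed != result_b.spec.seed
    ):
        raise ValueError("results were produced with different split seeds")
    diffs = result_a.per_split_auc - result_b.per_split_auc
    mean, low, high = corrected_resampled_ci(diffs, level=level)
    significant = not (low <= 0.0 <= high)
    return mean, (low, high), significant


def _align_labels(cohort: CohortTable, labels: OutcomeLabels | np.ndarray):
    """Restrict the cohort to labelled subjects; return (cohort_rows, y)."""
    if isinstance(labels, OutcomeLabels):
        lab = pd.Series(labels.labels, index=labels.subject_id)
        keep = cohort.data["subject_id"].isin(lab.index).to_numpy()
        data = cohort.data[keep].reset_index(drop=True)
        y = lab.loc[data["subject_id"]].to_numpy()
        sub = replace(cohort, data=data)
        return sub, y
    y = np.asarray(labels).astype(int)
    if len(y) != cohort.n_subjects:
        raise ValueError("label vector length does not match the cohort")
    return cohort, y


def _prepare(
    cohort: CohortTable,
    y: np.ndarray,
    spec: ExperimentSpec,
    hierarchy: HierarchySpec,
):
    """Variant handling shared by all splits: feature resolution, optional
    whole-data age correction and MRI selection, hierarchy pruning."""
    features = resolve_feature_set(spec.feature_set, cohort.feature_meta, hierarchy)
    if spec.model_variant in (2, 4):
        features = [f for f in features if f != "age"]
    if not features:
        raise ValueError("feature set is empty after variant handling")

    work = cohort
    corrected = None
    if spec.model_variant in (3, 4):
        to_correct = [
            f for f in features if f != "age" and not cohort.is_binary(f)
        ]
        if to_correct and spec.age_correction_scope == "full":
            model = fit_age_correction(cohort, to_correct)
            work = apply_age_correction(model, cohort)
        corrected = to_correct

    if spec.mri_selection_threshold is not None:
        mri = [f for f in features if work.category_of(f).split("/")[0] == "mri"]
        if mri:
            report = select_mri_features(
                work, y, mri_features=mri, threshold=spec.mri_selection_threshold
            )
            drop = set(report.dropped)
            features = [f for f in features if f not in drop]
    pruned = prune_hierarchy(hierarchy, set(features))
    if pruned is None:
        raise ValueError("no features left after selection")
    return work, pruned, corrected


def run_experiment(
    cohort: CohortTable,
    labels: OutcomeLabels | np.ndarray,
    spec: ExperimentSpec,
    hierarchy: HierarchySpec | None = None,
) -> CVResult:
    """Run one repeated stratified 2-fold CV experiment.

    For every split the hierarchy is fitted on the training half and the
    test half is scored; the test AUC and every top-level category's
    fitted relevance are recorded. Splits whose test half lacks a class or
    yields no scorable subject are recorded as NaN and excluded from the
    aggregate with a logged count.
    """
    if hierarchy is None:
        hierarchy = default_hierarchy()
    sub, y = _align_labels(cohort, labels)
    work, pruned, corrected = _prepare(sub, y, spec, hierarchy)
    X_all = work.feature_matrix(hierarchy_features(pruned))

    splits = stratified_2fold_splits(y, spec.n_repetitions, spec.seed)
    per_split = np.full(len(splits), np.nan)
    rel_rows = []
    for i, (train, test) in enumerate(splits):
        X_fit = X_all
        if (
            spec.model_variant in (3, 4)
            and spec.age_correction_scope == "fold"
            and corrected
        ):
            model = fit_age_correction(sub, corrected, rows=train)
            X_fit = apply_age_correction(model, sub).feature_matrix(
                hierarchy_features(pruned)
            )
        root = fit_hierarchy(X_fit.iloc[train], y[train], pruned)
        dsi = score_subjects(root, X_fit.iloc[test])
        try:
            per_split[i] = auc(dsi, y[test])
        except ValueError:
            logger.warning("split %d: AUC undefined (degenerate test half)", i)
        for cat, rel in root.top_level_relevances().items():
            rel_rows.append(
                {"repetition": i // 2, "fold": i % 2, "category": cat, "relevance": rel}
            )
    valid = per_split[~np.isnan(per_split)]
    mean, low, high = corrected_resampled_ci(valid)
    return CVResult(
        per_split_auc=per_split,
        mean_auc=mean,
        ci_low=low,
        ci_high=high,
        relevance_records=pd.DataFrame(rel_rows),
        spec=spec,
        n_excluded_splits=int(np.isnan(per_split).sum()),
    )


def cumulative_feature_sets(
    order: list[str], base_spec: ExperimentSpec | None = None
) -> list[ExperimentSpec]:
    """Specs for the nested prefixes of a category order (age; age+ct; ...)."""
    if len(order) != len(set(order)):
        raise ValueError("cumulative order contains duplicates")
    base = base_spec or ExperimentSpec()
    return [replace(base, feature_set=list(order[: i + 1])) for i in range(len(order))]


def selection_sweep(
    cohort: CohortTable,
    labels: OutcomeLabels | np.ndarray,
    feature_sets: dict[str, list[str]] | None = None,
    grid=None,
    base_spec: ExperimentSpec | None = None,
    hierarchy: HierarchySpec | None = None,
) -> pd.DataFrame:
    """Relevance-threshold sweep over the MRI features.

    For each threshold in ``grid`` (default 0.00 .. 0.10 in steps of 0.01)
    and each named feature set (default: all, all-minus-age, mri-only) the
    reduced 10x2-fold protocol is run with whole-dataset MRI relevance
    selection; one row per (feature_set, t) with mean AUC and CI.
    """
    from .preprocessing import DEFAULT_THRESHOLD_GRID

    if grid is None:
        grid = DEFAULT_THRESHOLD_GRID
    if feature_sets is None:
        feature_sets = {
            "all": ["all"],
            "all_but_age": ["all_but_age"],
            "mri_only": ["mri"],
        }
    base = base_spec or ExperimentSpec(n_repetitions=10)
    rows = []
    for name, fs in feature_sets.items():
        for t in grid:
            spec = replace(base, feature_set=list(fs), mri_selection_threshold=float(t))
            try:
                res = run_experiment(cohort, labels, spec, hierarchy=hierarchy)
                stats = (res.mean_auc, res.ci_low, res.ci_high)
            except ValueError:
                # e.g. an MRI-only set emptied by the threshold: undefined row
                logger.warning(
                    "feature set %r at t=%.2f leaves nothing to evaluate", name, t
                )
                stats = (float("nan"),) * 3
            rows.append(
                {
                    "feature_set": name,
                    "threshold": float(t),
                    "mean_auc": stats[0],
                    "ci_low": stats[1],
                    "ci_high": stats[2],
                }
            )
    return pd.DataFrame(rows)


def extreme_subgroup_auc(
    dsi_scores, labels, low: float = 0.2, high: float = 0.8
) -> tuple[float, int, float]:
    """AUC restricted to confidently-scored subjects (DSI < low or > high).

    Returns (auc, n_retained, fraction_retained); the AUC is NaN when the
    retained subset lacks a class (counts are still reported).
    """
    s = np.asarray(dsi_scores, dtype=float)
    y = np.asarray(labels).astype(int)
    ok = ~np.isnan(s)
    keep = ok & ((s < low) | (s > high))
    n_ret = int(keep.sum())
    frac = n_ret / len(s) if len(s) else float("nan")
    try:
        value = auc(s[keep], y[keep]) if n_ret else float("nan")
    except ValueError:
        value = float("nan")
    return value, n_ret, frac
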