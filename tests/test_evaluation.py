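"""Cross-validation protocol: splits, AUC, corrected CI, experiments."""

import numpy as np
import pandas as pd
import pytest

import dsidx
from dsidx.evaluation import (
    ExperimentSpec,
    auc,
    compare_aucs,
    corrected_resampled_ci,
    cumulative_feature_sets,
    extreme_subgroup_auc,
    run_experiment,
    stratified_2fold_splits,
)

from _oracles import pair_auc


class TestSplits:
    def test_exact_stratification(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        for train, test in stratified_2fold_splits(y, 5, seed=0):
            assert y[train].sum() == 2 and y[test].sum() == 2
            assert len(train) == len(test) == 4

    def test_imbalanced_fold_sizes_differ_by_at_most_one(self):
        y = np.zeros(2542, dtype=int)
        y[:127] = 1
        splits = stratified_2fold_splits(y, 3, seed=1)
        for train, test in splits:
            p_tr, p_te = int(y[train].sum()), int(y[test].sum())
            assert {p_tr, p_te} == {63, 64}
            assert {len(train) - p_tr, len(test) - p_te} == {1207, 1208}
            assert sorted(np.concatenate([train, test])) == list(range(2542))

    def test_both_fold_orders_emitted(self):
        y = np.array([1, 1, 0, 0] * 3)
        splits = stratified_2fold_splits(y, 2, seed=3)
        assert len(splits) == 4
        a, b = splits[0]
        b2, a2 = splits[1]
        np.testing.assert_array_equal(a, a2)
        np.testing.assert_array_equal(b, b2)

    def test_seeded_determinism(self):
        y = np.array([1, 1, 0, 0, 0, 1])
        s1 = stratified_2fold_splits(y, 4, seed=9)
        s2 = stratified_2fold_splits(y, 4, seed=9)
        for (a1, b1), (a2, b2) in zip(s1, s2):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(b1, b2)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_2fold_splits(np.array([1, 0, 0, 0]), 1, seed=0)


class TestAuc:
    def test_perfect_and_chance(self):
        assert auc([4, 5, 1, 2], [1, 1, 0, 0]) == 1.0
        assert auc([3, 3, 3, 3], [1, 1, 0, 0]) == 0.5

    def test_enumerated_example(self):
        assert auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_matches_pair_enumeration_with_ties(self, rng):
        scores = rng.integers(0, 5, 60).astype(float)
        y = (rng.random(60) < 0.4).astype(int)
        expected = pair_auc(scores[y == 1], scores[y == 0])
        assert auc(scores, y) == pytest.approx(expected)

    def test_missing_scores_excluded(self):
        assert auc([0.9, np.nan, 0.5, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_class_flagged(self):
        with pytest.raises(ValueError):
            auc([0.2, 0.4], [1, 1])


class TestCorrectedCI:
    def test_hand_evaluated_two_value_case(self):
        """{0.7, 0.8} at k=2, r=1: m=0.75, s2=0.005, corrected var 0.0075,
        half-width 12.706 * 0.086603 = 1.1003."""
        m, lo, hi = corrected_resampled_ci([0.7, 0.8], k_folds=2, r_repetitions=1)
        assert m == pytest.approx(0.75)
        assert hi - m == pytest.approx(12.7062047 * np.sqrt(0.0075), rel=1e-5)
        assert m - lo == pytest.approx(hi - m)

    def test_constant_input_zero_width(self):
        m, lo, hi = corrected_resampled_ci([0.6] * 10)
        assert m == pytest.approx(0.6)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            corrected_resampled_ci([0.5])
        with pytest.raises(ValueError):
            corrected_resampled_ci([0.5, 0.6, 0.7], k_folds=2, r_repetitions=2)

    def test_coverage_is_conservative_for_iid_values(self, rng):
        """On iid values (no training-set overlap) the corrected interval
        over-covers the true mean: coverage must exceed the nominal 95%."""
        true_mean = 0.7
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            v = true_mean + 0.05 * rng.standard_normal(20)
            _, lo, hi = corrected_resampled_ci(v)
            hits += lo <= true_mean <= hi
        assert hits / n_sim >= 0.95

    def test_wider_than_naive_t_interval(self, rng):
        from scipy.stats import t as t_dist

        v = 0.7 + 0.05 * rng.standard_normal(50)
        _, lo, hi = corrected_resampled_ci(v)
        naive_half = t_dist.ppf(0.975, 49) * np.std(v, ddof=1) / np.sqrt(50)
        assert (hi - lo) / 2 > naive_half


class TestCompare:
    def _result(self, values, seed=0):
        from dsidx.evaluation import CVResult

        v = np.asarray(values, dtype=float)
        m, lo, hi = corrected_resampled_ci(v)
        return CVResult(
            per_split_auc=v,
            mean_auc=m,
            ci_low=lo,
            ci_high=hi,
            relevance_records=pd.DataFrame(),
            spec=ExperimentSpec(seed=seed, n_repetitions=len(v) // 2),
        )

    def test_self_comparison_never_significant(self, rng):
        r = self._result(rng.uniform(0.6, 0.9, 20))
        diff, ci, sig = compare_aucs(r, r)
        assert diff == 0.0 and not sig

    def test_far_apart_distributions_significant(self):
        a = self._result(np.linspace(0.90, 0.92, 10))
        b = self._result(np.linspace(0.50, 0.52, 10))
        diff, ci, sig = compare_aucs(a, b)
        assert sig and diff == pytest.approx(0.40, abs=0.01)

    def test_mismatched_results_rejected(self, rng):
        a = self._result(rng.uniform(0, 1, 10))
        b = self._result(rng.uniform(0, 1, 8))
        with pytest.raises(ValueError):
            compare_aucs(a, b)
        c = self._result(rng.uniform(0, 1, 10), seed=5)
        with pytest.raises(ValueError, match="seed"):
            compare_aucs(a, c)


class TestExperiments:
    def test_age_only_dsi_tracks_raw_age_auc(self, small_cohort, small_labels):
        """A single-feature DSI is a monotone transform of the feature, so
        each split's test AUC matches the AUC of raw age on that test half
        (up to score collapse at the support edges)."""
        spec = ExperimentSpec(feature_set=["age"], n_repetitions=3, seed=21)
        res = run_experiment(small_cohort, small_labels, spec)
        y = small_labels.labels
        splits = stratified_2fold_splits(y, 3, seed=21)
        age = small_cohort.data["age"].to_numpy()
        for i, (_, test) in enumerate(splits):
            raw = auc(age[test], y[test])
            assert res.per_split_auc[i] == pytest.approx(raw, abs=0.02)

    def test_variant_excludes_age(self, small_cohort, small_labels):
        spec = ExperimentSpec(feature_set=["all"], model_variant=2,
                              n_repetitions=1, seed=0)
        res = run_experiment(small_cohort, small_labels, spec)
        cats = set(res.relevance_records["category"])
        assert "age" not in cats and "mri" in cats
        with pytest.raises(ValueError):
            run_experiment(
                small_cohort,
                small_labels,
                ExperimentSpec(feature_set=["age"], model_variant=4,
                               n_repetitions=1, seed=0),
            )

    def test_result_shape_and_ci_ordering(self, small_cohort, small_labels):
        spec = ExperimentSpec(feature_set=["age", "mri"], n_repetitions=4, seed=2)
        res = run_experiment(small_cohort, small_labels, spec)
        assert len(res.per_split_auc) == 8
        assert res.ci_low <= res.mean_auc <= res.ci_high
        assert set(res.relevance_records["category"]) == {"age", "mri"}
        assert len(res.relevance_records) == 8 * 2

    def test_determinism(self, small_cohort, small_labels):
        spec = ExperimentSpec(feature_set=["age", "ct"], n_repetitions=2, seed=13)
        r1 = run_experiment(small_cohort, small_labels, spec)
        r2 = run_experiment(small_cohort, small_labels, spec)
        np.testing.assert_array_equal(r1.per_split_auc, r2.per_split_auc)
        pd.testing.assert_frame_equal(r1.relevance_records, r2.relevance_records)

    def test_fold_scope_age_correction_runs(self, small_cohort, small_labels):
        spec = ExperimentSpec(
            feature_set=["mri"], model_variant=3, n_repetitions=1, seed=4,
            age_correction_scope="fold",
        )
        res = run_experiment(small_cohort, small_labels, spec)
        assert np.isfinite(res.mean_auc)

    def test_noise_features_degrade_gracefully(self, small_cohort, small_labels, rng):
        """Relevance weighting bounds the damage: 50 pure-noise features
        added to age cost well under 0.15 AUC."""
        c = small_cohort.copy()
        noise = {f"noise_{i:02d}": rng.standard_normal(c.n_subjects) for i in range(50)}
        c.data = pd.concat([c.data, pd.DataFrame(noise)], axis=1)
        c.feature_meta = pd.concat(
            [
                c.feature_meta,
                pd.DataFrame(
                    [
                        {"feature": k, "category_path": "noise", "is_binary": False}
                        for k in noise
                    ]
                ),
            ],
            ignore_index=True,
        )
        from dsidx.hierarchy import hierarchy_from_meta

        h = hierarchy_from_meta(c.feature_meta)
        base = run_experiment(
            c, small_labels, ExperimentSpec(feature_set=["age"],
                                            n_repetitions=5, seed=8), hierarchy=h
        )
        noisy = run_experiment(
            c, small_labels, ExperimentSpec(feature_set=["age", "noise"],
                                            n_repetitions=5, seed=8), hierarchy=h
        )
        assert base.mean_auc - noisy.mean_auc < 0.15


class TestCumulative:
    def test_prefix_construction(self):
        specs = cumulative_feature_sets(["age", "ct", "cvr", "mri", "gen", "edu"])
        assert len(specs) == 6
        assert specs[0].feature_set == ["age"]
        for a, b in zip(specs, specs[1:]):
            assert set(a.feature_set) < set(b.feature_set)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            cumulative_feature_sets(["age", "age"])

    def test_unknown_category_rejected(self, small_cohort, small_labels):
        spec = cumulative_feature_sets(["age", "not_a_category"])[1]
        with pytest.raises(Exception, match="not_a_category"):
            run_experiment(small_cohort, small_labels, spec)


class TestSubgroup:
    def test_empty_window_retains_no_one(self, rng):
        s = rng.uniform(0.3, 0.7, 50)
        y = (rng.random(50) < 0.5).astype(int)
        value, n_ret, frac = extreme_subgroup_auc(s, y, low=0.0, high=1.0)
        assert n_ret == 0 and np.isnan(value)

    def test_vacuous_window_equals_full_auc(self, rng):
        s = rng.uniform(0, 1, 80)
        s = np.where(np.isclose(s, 0.5), 0.51, s)
        y = (s + 0.2 * rng.standard_normal(80) > 0.5).astype(int)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        value, n_ret, frac = extreme_subgroup_auc(s, y, low=0.5, high=0.5)
        assert n_ret == 80 and frac == 1.0
        assert value == pytest.approx(auc(s, y))

    def test_one_class_subset_reports_counts(self):
        s = np.array([0.1, 0.15, 0.9])
        y = np.array([0, 0, 0])
        value, n_ret, frac = extreme_subgroup_auc(s, np.array([0, 0, 1]), 0.2, 0.95)
        assert n_ret == 2 and np.isnan(value)
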