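"""Fit the Disease State Index hierarchy and score subjects, including one
with missing data — the index simply renormalises over what is observed."""

import numpy as np

import dsidx

cohort = dsidx.generate_cohort(dsidx.default_config(n_subjects=1500, seed=8))
gmodel = dsidx.fit_gfactor(cohort.baseline_tests())
labels = dsidx.label_decline(
    dsidx.score_gfactor(gmodel, cohort.baseline_tests()),
    dsidx.score_gfactor(gmodel, cohort.followup_tests()),
    cohort.data["followup_years"].to_numpy(),
    subject_id=cohort.data["subject_id"].to_numpy(),
)

hierarchy = dsidx.prune_hierarchy(dsidx.default_hierarchy(), set(cohort.feature_names))
root = dsidx.fit_hierarchy(cohort.data, labels.labels, hierarchy)

print("top-level category relevances (Youden weight of each branch):")
for cat, rel in sorted(root.top_level_relevances().items(), key=lambda kv: -kv[1]):
    print(f"  {cat:18s} {rel:.2f}")

dsi = dsidx.score_subjects(root, cohort.data)
calls = dsidx.classify(dsi)
print(f"\nDSI range: [{np.nanmin(dsi):.2f}, {np.nanmax(dsi):.2f}]; "
      f"{(calls == 'positive').sum()} subjects called positive (DSI > 0.5)")

# knock out every MRI feature for one subject: the index still scores them
one = cohort.data.iloc[[0]].copy()
one[cohort.features_in_category("mri")] = np.nan
with_mri = dsi[0]
without_mri = dsidx.score_subjects(root, one)[0]
print(f"subject 1 DSI with MRI {with_mri:.3f} vs without MRI {without_mri:.3f} "
      "(missing branches are skipped, weights renormalised)")
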