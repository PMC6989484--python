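"""Two robustness analyses: restricting calls to extreme DSI values, and
blanking a block of features for a sub-cohort (as when one sub-study's
diffusion MRI was acquired years later)."""

import dsidx
from dsidx.evaluation import auc, extreme_subgroup_auc, stratified_2fold_splits

cohort = dsidx.generate_cohort(dsidx.default_config(n_subjects=2542, seed=4))
gmodel = dsidx.fit_gfactor(cohort.baseline_tests())
labels = dsidx.label_decline(
    dsidx.score_gfactor(gmodel, cohort.baseline_tests()),
    dsidx.score_gfactor(gmodel, cohort.followup_tests()),
    cohort.data["followup_years"].to_numpy(),
    subject_id=cohort.data["subject_id"].to_numpy(),
)
y = labels.labels

# --- extreme-DSI subgroup on a held-out half ----------------------------
train, test = stratified_2fold_splits(y, 1, seed=11)[0]
spec = {"name": "root", "children": [{"feature": "age"}]}
X = cohort.feature_matrix(["age"])
root = dsidx.fit_hierarchy(X.iloc[train], y[train], spec)
dsi = dsidx.score_subjects(root, X.iloc[test])
full = auc(dsi, y[test])
sub, n_ret, frac = extreme_subgroup_auc(dsi, y[test], low=0.2, high=0.8)
print(f"held-out AUC, everyone:            {full:.3f}  (n={len(test)})")
print(f"held-out AUC, DSI<0.2 or >0.8:     {sub:.3f}  (n={n_ret}, {100*frac:.0f}% retained)")
# Subjects near the 0.5 boundary are the hardest; refusing to call them
# raises discrimination on the remainder.

# --- masking a sub-cohort's diffusion features --------------------------
masked = dsidx.mask_subset_features(
    cohort, ["global_fa", "global_md"], n_subjects_masked=680, seed=1
)
h = dsidx.prune_hierarchy(dsidx.default_hierarchy(), set(cohort.feature_names))
root_m = dsidx.fit_hierarchy(masked.data.iloc[train], y[train], h)
dsi_m = dsidx.score_subjects(root_m, masked.data.iloc[test])
print(f"all-features AUC with 680 subjects' diffusion MRI masked: "
      f"{auc(dsi_m, y[test]):.3f} (missing data tolerated, not imputed)")
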