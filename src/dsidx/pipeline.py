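"""End-to-end pipeline: generate (or ingest) → g-factor → label → evaluate → report.

One global seed fans out deterministically to stage-specific child seeds
(recorded in the manifest) so any stage can be rerun in isolation. All
tabular artifacts are CSV and all summaries JSON, for auditability.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import CohortTable, read_cohort
from .evaluation import ExperimentSpec, run_experiment
from .gfactor import fit_gfactor, label_decline, score_gfactor
from .hierarchy import default_hierarchy, load_hierarchy
from .synthetic import default_config, generate_cohort, load_config


@dataclass
class RunManifest:
    version: str
    seed: int
    child_seeds: dict[str, int]
    config_digests: dict[str, str]
    outputs: dict[str, str]
    counts: dict[str, int]
    settings: dict
    started: str = ""
    finished: str = ""
    summaries: dict = field(default_factory=dict)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _digest(path: str | None) -> str:
    if path is None:
        return "builtin-default"
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def child_seeds(seed: int, names: tuple[str, ...]) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31, derived from one global seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(
    out_dir: str,
    seed: int = 0,
    n_subjects: int | None = None,
    n_repetitions: int = 10,
    variants: tuple[int, ...] = (1, 2, 3, 4),
    feature_set: list[str] | None = None,
    tail_fraction: float = 0.05,
    mri_selection_threshold: float | None = None,
    config_path: str | None = None,
    hierarchy_path: str | None = None,
    cohort_prefix: str | None = None,
) -> RunManifest:
    """Execute the full analysis and write all artifacts under ``out_dir``.

    Either generates a synthetic cohort (default or ``config_path``) or
    ingests one from ``cohort_prefix``. Deterministic given ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    seeds = child_seeds(seed, ("generate", "evaluate"))

    if cohort_prefix is not None:
        cohort: CohortTable = read_cohort(cohort_prefix)
        stage = "ingest"
    else:
        cfg = load_config(config_path) if config_path else default_config()
        if n_subjects is not None:
            cfg.n_subjects = n_subjects
        cfg.seed = seeds["generate"]
        cohort = generate_cohort(cfg)
        stage = "generate"
    cohort_paths = cohort.write(str(out / "cohort"))

    gmodel = fit_gfactor(cohort.baseline_tests())
    g0 = score_gfactor(gmodel, cohort.baseline_tests())
    g1 = score_gfactor(gmodel, cohort.followup_tests())
    labels = label_decline(
        g0,
        g1,
        cohort.data["followup_years"].to_numpy(),
        subject_id=cohort.data["subject_id"].to_numpy(),
        tail_fraction=tail_fraction,
    )
    labels_path = out / "labels.csv"
    labels.frame().to_csv(labels_path, index=False)

    hierarchy = load_hierarchy(hierarchy_path) if hierarchy_path else default_hierarchy()
    summaries: dict = {
        "gfactor": {
            "explained_variance_share": gmodel.explained_variance_share,
            "n_fit": gmodel.n_fit,
            "n_excluded": gmodel.n_excluded,
        },
        "labels": {
            "n_positive": labels.n_positive,
            "n_negative": labels.n_negative,
            "threshold_delta_g_per_year": labels.threshold,
        },
        "variants": {},
    }
    outputs = {
        "cohort": cohort_paths[0],
        "cohort_features": cohort_paths[1],
        "labels": str(labels_path),
    }
    for variant in variants:
        spec = ExperimentSpec(
            feature_set=feature_set or ["all"],
            model_variant=variant,
            n_repetitions=n_repetitions,
            seed=seeds["evaluate"],
            mri_selection_threshold=mri_selection_threshold,
        )
        result = run_experiment(cohort, labels, spec, hierarchy=hierarchy)
        split_path = out / f"auc_splits_variant{variant}.csv"
        np.savetxt(
            split_path,
            result.per_split_auc,
            header="auc",
            comments="",
            delimiter=",",
        )
        rel_path = out / f"relevance_variant{variant}.csv"
        result.relevance_records.to_csv(rel_path, index=False)
        summaries["variants"][str(variant)] = result.summary() | {
            "feature_set": spec.feature_set,
            "mri_selection_threshold": spec.mri_selection_threshold,
        }
        outputs[f"auc_splits_variant{variant}"] = str(split_path)
        outputs[f"relevance_variant{variant}"] = str(rel_path)

    manifest = RunManifest(
        version=__version__,
        seed=seed,
        child_seeds=seeds,
        config_digests={
            "generator_config": _digest(config_path),
            "hierarchy": _digest(hierarchy_path),
        },
        outputs=outputs,
        counts={
            "n_subjects": cohort.n_subjects,
            "n_features": len(cohort.feature_names),
            "n_labelled": labels.n_positive + labels.n_negative,
        },
        settings={
            "stage": stage,
            "n_repetitions": n_repetitions,
            "variants": list(variants),
            "tail_fraction": tail_fraction,
            "mri_selection_threshold": mri_selection_threshold,
            "feature_set": feature_set or ["all"],
        },
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        summaries=summaries,
    )
    manifest.write(str(out / "manifest.json"))
    missing = [p for p in outputs.values() if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"pipeline finished but outputs are missing: {missing}")
    return manifest
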