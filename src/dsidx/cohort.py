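"""Cohort container and plain-CSV I/O.

A cohort is a subject-by-feature table with explicit missingness (NaN in
memory, empty cells on disk) plus a sidecar metadata table assigning every
predictor feature a position in the category hierarchy and a binary flag.
Core demographic columns (age, sex, follow-up interval) and the two-visit
cognitive test scores live alongside the predictor features; ``age`` and
``sex`` and the baseline test scores double as predictors and therefore
also appear in the feature metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: columns every cohort table must carry besides tests and features
CORE_COLUMNS = ("subject_id", "age", "sex", "followup_years")

#: suffix marking the follow-up visit's score column for a cognitive test
FOLLOWUP_SUFFIX = "_followup"

META_COLUMNS = ("feature", "category_path", "is_binary")


class CohortError(ValueError):
    """Raised for malformed cohort tables or metadata."""


@dataclass
class CohortTable:
    """Subject-by-feature table plus per-feature hierarchy metadata.

    Parameters
    ----------
    data
        One row per subject. Must contain ``subject_id``, ``age``, ``sex``
        (female = 1), ``followup_years``, one column per cognitive test at
        baseline (named after the test) and at follow-up (test name +
        ``_followup``), and one column per predictor feature. Missing
        values are NaN.
    feature_meta
        One row per predictor feature: ``feature`` (column name in
        ``data``), ``category_path`` (slash-separated path from the
        hierarchy root, e.g. ``mri/tissue_volumes``) and ``is_binary``.
    test_names
        Names of the cognitive tests entering the g-factor.
    """

    data: pd.DataFrame
    feature_meta: pd.DataFrame
    test_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise CohortError(f"cohort table lacks core columns: {missing}")
        if self.data["subject_id"].duplicated().any():
            dupes = self.data.loc[self.data["subject_id"].duplicated(), "subject_id"]
            raise CohortError(f"duplicate subject_id values: {sorted(set(dupes))[:5]}")
        for c in META_COLUMNS:
            if c not in self.feature_meta.columns:
                raise CohortError(f"feature metadata lacks column {c!r}")
        if self.feature_meta["feature"].duplicated().any():
            dupes = self.feature_meta.loc[
                self.feature_meta["feature"].duplicated(), "feature"
            ]
            raise CohortError(f"features listed twice in metadata: {list(dupes)}")
        absent = [f for f in self.feature_meta["feature"] if f not in self.data.columns]
        if absent:
            raise CohortError(f"features absent from the data table: {absent}")
        for t in self.test_names:
            for col in (t, t + FOLLOWUP_SUFFIX):
                if col not in self.data.columns:
                    raise CohortError(f"cognitive test column {col!r} missing")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.feature_meta["feature"])

    def is_binary(self, feature: str) -> bool:
        row = self.feature_meta.loc[self.feature_meta["feature"] == feature]
        if row.empty:
            raise CohortError(f"unknown feature {feature!r}")
        return bool(row["is_binary"].iloc[0])

    def category_of(self, feature: str) -> str:
        row = self.feature_meta.loc[self.feature_meta["feature"] == feature]
        if row.empty:
            raise CohortError(f"unknown feature {feature!r}")
        return str(row["category_path"].iloc[0])

    def features_in_category(self, category: str) -> list[str]:
        """All features whose category path equals or descends from ``category``."""
        paths = self.feature_meta["category_path"].astype(str)
        hit = (paths == category) | paths.str.startswith(category + "/")
        return list(self.feature_meta.loc[hit, "feature"])

    def baseline_tests(self) -> pd.DataFrame:
        return self.data[self.test_names]

    def followup_tests(self) -> pd.DataFrame:
        df = self.data[[t + FOLLOWUP_SUFFIX for t in self.test_names]].copy()
        df.columns = self.test_names
        return df

    def feature_matrix(self, features: list[str] | None = None) -> pd.DataFrame:
        return self.data[features if features is not None else self.feature_names]

    def copy(self) -> "CohortTable":
        return replace(
            self,
            data=self.data.copy(),
            feature_meta=self.feature_meta.copy(),
            test_names=list(self.test_names),
        )

    # -- persistence -----------------------------------------------------------

    def write(self, prefix: str) -> tuple[str, str]:
        """Write ``<prefix>.csv`` and ``<prefix>.features.csv``; empty cell = missing."""
        data_path = f"{prefix}.csv"
        meta_path = f"{prefix}.features.csv"
        self.data.to_csv(data_path, index=False, na_rep="")
        meta = self.feature_meta.copy()
        meta["is_binary"] = meta["is_binary"].astype(int)
        meta.to_csv(meta_path, index=False)
        return data_path, meta_path


def read_cohort(prefix: str, test_names: list[str] | None = None) -> CohortTable:
    """Read a cohort written by :meth:`CohortTable.write`.

    Cognitive test names are inferred from paired ``<name>``/``<name>_followup``
    columns when not given explicitly. Validation failures raise
    :class:`CohortError` naming the offending rows or columns.
    """
    data_path = f"{prefix}.csv"
    meta_path = f"{prefix}.features.csv"
    try:
        meta = pd.read_csv(meta_path)
    except FileNotFoundError as exc:
        raise CohortError(f"sidecar feature metadata not found: {meta_path}") from exc
    data = pd.read_csv(data_path)
    meta["is_binary"] = meta["is_binary"].astype(bool)
    if test_names is None:
        test_names = [
            c.removesuffix(FOLLOWUP_SUFFIX)
            for c in data.columns
            if c.endswith(FOLLOWUP_SUFFIX)
            and c.removesuffix(FOLLOWUP_SUFFIX) in data.columns
        ]
    non_numeric = [
        c
        for c in data.columns
        if c != "subject_id" and not np.issubdtype(data[c].dtype, np.number)
    ]
    if non_numeric:
        raise CohortError(f"non-numeric cells in columns: {non_numeric}")
    return CohortTable(data=data, feature_meta=meta, test_names=test_names)
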