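"""Age correction and relevance-based MRI feature selection.

Non-binary features are residualised on age with per-feature ordinary
least squares, removing the linear age component so that what remains is
age-independent signal. Selection thresholds MRI features on their
univariate relevance computed on the entire dataset before training — the
protocol this mirrors does the same and flags it as an optimistic choice;
a leakage-safe per-fold variant of the age correction is available via
``scope="fold"`` in the evaluation layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .dsi import fit_feature
from .gfactor import OutcomeLabels


@dataclass
class AgeCorrectionModel:
    """Per-feature OLS intercept/slope of feature on age."""

    coefficients: pd.DataFrame  # index=feature, columns=intercept, slope, n_fit
    age_mean_reference: float | None = None

    @property
    def features(self) -> list[str]:
        return list(self.coefficients.index)


def fit_age_correction(
    cohort: CohortTable,
    features: list[str] | None = None,
    rows: np.ndarray | None = None,
) -> AgeCorrectionModel:
    """Fit feature ~ intercept + slope*age per non-binary feature.

    Missing values are skipped per feature; each feature needs >= 3
    non-missing (value, age) pairs. Binary features are refused: an OLS
    residual of a 0/1 feature is not a meaningful quantity here.
    ``rows`` (boolean mask or positional indices) restricts the fit sample,
    e.g. to a training fold for the leakage-safe variant; the default uses
    the whole cohort, mirroring the single-pass protocol.
    """
    if features is None:
        features = [
            f for f in cohort.feature_names if not cohort.is_binary(f) and f != "age"
        ]
    binary = [f for f in features if cohort.is_binary(f)]
    if binary:
        raise ValueError(f"refusing to age-correct binary features: {binary}")
    if rows is None:
        frame = cohort.data
    else:
        rows = np.asarray(rows)
        frame = cohort.data[rows] if rows.dtype == bool else cohort.data.iloc[rows]
    age = frame["age"].to_numpy(dtype=float)
    fits = {}
    for f in features:
        vals = frame[f].to_numpy(dtype=float)
        ok = ~(np.isnan(vals) | np.isnan(age))
        if ok.sum() < 3:
            raise ValueError(f"feature {f!r}: fewer than 3 non-missing pairs")
        a = age[ok]
        if np.ptp(a) == 0:
            raise ValueError(f"feature {f!r}: age is constant in the fit sample")
        slope, intercept = np.polyfit(a, vals[ok], 1)
        fits[f] = {"intercept": intercept, "slope": slope, "n_fit": int(ok.sum())}
    coef = pd.DataFrame.from_dict(fits, orient="index")
    coef.index.name = "feature"
    return AgeCorrectionModel(coefficients=coef)


def apply_age_correction(model: AgeCorrectionModel, cohort: CohortTable) -> CohortTable:
    """Replace each covered non-missing cell by its residual from the age fit.

    Binary features and ``age`` itself are untouched; missing stays missing.
    """
    out = cohort.copy()
    age = out.data["age"].to_numpy(dtype=float)
    for f in model.features:
        if f not in out.data.columns:
            raise ValueError(f"correction model covers unknown feature {f!r}")
        ic = model.coefficients.loc[f, "intercept"]
        sl = model.coefficients.loc[f, "slope"]
        out.data[f] = out.data[f].to_numpy(dtype=float) - (ic + sl * age)
    return out


@dataclass
class SelectionReport:
    threshold: float
    relevance: pd.Series  # per MRI feature, whole-dataset univariate relevance
    retained: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.relevance.index,
                "relevance": self.relevance.to_numpy(),
                "retained": [f in set(self.retained) for f in self.relevance.index],
            }
        )


def feature_relevance(values: np.ndarray, labels: np.ndarray) -> float:
    """Univariate relevance (clamped Youden index of the fitness classifier)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    return fit_feature(values[labels == 1], values[labels == 0]).relevance


def select_mri_features(
    cohort: CohortTable,
    labels: OutcomeLabels | np.ndarray,
    mri_features: list[str] | None = None,
    threshold: float = 0.0,
) -> SelectionReport:
    """Retain MRI features whose whole-dataset relevance is >= threshold.

    The relevance is computed on all labelled subjects, before any split —
    deliberately matching the evaluated protocol, which treats the
    resulting optimism as an upper bound. If nothing survives, a warning
    is emitted and the retained list is empty (the classifier tolerates an
    absent branch).
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    if mri_features is None:
        mri_features = cohort.features_in_category("mri")
    if isinstance(labels, OutcomeLabels):
        keep = cohort.data["subject_id"].isin(labels.subject_id).to_numpy()
        X = cohort.data[keep]
        lab = pd.Series(labels.labels, index=labels.subject_id)
        y = lab.loc[X["subject_id"]].to_numpy()
    else:
        y = np.asarray(labels)
        X = cohort.data
    rel = pd.Series(
        {f: feature_relevance(X[f].to_numpy(dtype=float), y) for f in mri_features},
        name="relevance",
    )
    retained = [f for f in mri_features if rel[f] >= threshold]
    dropped = [f for f in mri_features if f not in retained]
    if mri_features and not retained:
        warnings.warn(
            f"relevance threshold {threshold} drops every MRI feature; "
            "the MRI branch will be absent",
            stacklevel=2,
        )
    return SelectionReport(
        threshold=threshold, relevance=rel, retained=retained, dropped=dropped
    )


#: default threshold grid for the selection sweep
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.0, 0.101, 0.01), 2))
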