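"""General cognitive factor (g-factor) and the decline outcome label.

The g-factor is the first unrotated principal component of a battery of
cognitive tests — here, by default, five: Stroop interference, letter-digit
substitution, verbal fluency, delayed recall of the 15-word learning test
and Purdue pegboard. The component is extracted from the correlation
matrix (the tests have incommensurate units), the loadings have unit norm,
and the sign is fixed so that the delayed-recall loading is positive:
higher g = better cognition.

Annualised decline is (g_followup - g_baseline) / followup_years, with the
baseline standardisation and loadings reused for the follow-up visit so
the difference is taken in a single, interpretable metric. The binary
outcome marks the ``tail_fraction`` (default 5%) of subjects with the
most negative annual change — the steepest decliners — as positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DELAYED_RECALL_DEFAULT = "wlt_delayed_recall"


@dataclass
class GFactorModel:
    test_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # unit Euclidean norm, oriented
    explained_variance_share: float
    orientation: int  # sign flip applied to the raw eigenvector
    n_fit: int = 0
    n_excluded: int = 0


def fit_gfactor(
    baseline_tests: pd.DataFrame,
    anchor_test: str | None = None,
) -> GFactorModel:
    """Fit the g-factor on baseline test scores.

    Subjects with any missing test are excluded from the fit (listwise)
    and counted in ``n_excluded``. Each test is z-scored on the fit
    sample; the loadings are the first eigenvector of the correlation
    matrix and the explained-variance share its eigenvalue divided by the
    number of tests.

    ``anchor_test`` names the test whose loading is forced positive
    (default: the delayed-recall test if present, else the first test).
    """
    tests = list(baseline_tests.columns)
    X = baseline_tests.to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    if len(Xc) < len(tests) + 1:
        raise ValueError(
            f"need at least {len(tests) + 1} complete subjects, got {len(Xc)}"
        )
    means = Xc.mean(axis=0)
    sds = Xc.std(axis=0, ddof=1)
    spread = np.ptp(Xc, axis=0)
    if np.any(spread == 0):
        constant = [t for t, s in zip(tests, spread) if s == 0]
        raise ValueError(f"constant test scores: {constant}")
    Z = (Xc - means) / sds
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    loadings = eigvec[:, -1]
    share = float(eigval[-1] / len(tests))
    if anchor_test is None:
        anchor_test = DELAYED_RECALL_DEFAULT if DELAYED_RECALL_DEFAULT in tests else tests[0]
    orientation = 1 if loadings[tests.index(anchor_test)] >= 0 else -1
    return GFactorModel(
        test_names=tests,
        means=means,
        sds=sds,
        loadings=orientation * loadings,
        explained_variance_share=share,
        orientation=orientation,
        n_fit=int(complete.sum()),
        n_excluded=int((~complete).sum()),
    )


def score_gfactor(model: GFactorModel, tests: pd.DataFrame) -> np.ndarray:
    """Project any visit's scores with the baseline standardisation and loadings.

    Returns one g per subject; NaN when any test score is missing.
    """
    X = tests[model.test_names].to_numpy(dtype=float)
    Z = (X - model.means) / model.sds
    g = Z @ model.loadings
    g[np.isnan(X).any(axis=1)] = np.nan
    return g


@dataclass
class OutcomeLabels:
    """5%-tail decline labels plus the per-subject annualised delta-g."""

    subject_id: np.ndarray
    delta_g_per_year: np.ndarray
    labels: np.ndarray  # 1 = significant decline
    threshold: float
    n_positive: int
    n_negative: int
    excluded_subjects: np.ndarray = field(default_factory=lambda: np.array([]))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "delta_g_per_year": self.delta_g_per_year,
                "label": self.labels,
            }
        )


def label_decline(
    g_baseline,
    g_followup,
    followup_years,
    subject_id=None,
    tail_fraction: float = 0.05,
) -> OutcomeLabels:
    """Label the steepest-declining tail of the cohort as positive.

    delta_g_per_year = (g_followup - g_baseline) / followup_years; the
    floor(tail_fraction * n) subjects with the most negative values are
    positive. The reported threshold is the largest (least negative) delta
    among the positives. Ties exactly at the cut are broken by ascending
    subject id, so the labelling is deterministic. Subjects with missing g
    at either visit are excluded before ranking and reported in
    ``excluded_subjects``.
    """
    g0 = np.asarray(g_baseline, dtype=float)
    g1 = np.asarray(g_followup, dtype=float)
    years = np.asarray(followup_years, dtype=float)
    if subject_id is None:
        subject_id = np.arange(len(g0))
    subject_id = np.asarray(subject_id)
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    usable = ~(np.isnan(g0) | np.isnan(g1))
    if np.any(years[usable] <= 0):
        raise ValueError("followup_years must be positive for labelled subjects")
    excluded = subject_id[~usable]
    sid = subject_id[usable]
    delta = (g1[usable] - g0[usable]) / years[usable]
    n = len(delta)
    n_pos = int(np.floor(tail_fraction * n))
    order = np.lexsort((sid, delta))  # most negative first; ties by subject id
    labels = np.zeros(n, dtype=int)
    labels[order[:n_pos]] = 1
    threshold = float(delta[order[n_pos - 1]]) if n_pos > 0 else float("nan")
    return OutcomeLabels(
        subject_id=sid,
        delta_g_per_year=delta,
        labels=labels,
        threshold=threshold,
        n_positive=n_pos,
        n_negative=n - n_pos,
        excluded_subjects=excluded,
    )
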