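"""The Disease State Index classifier.

The DSI is an ensemble of univariate empirical classifiers. For each
feature a *fitness function* maps a raw value ``x`` to a class-membership
score in [0, 1] built from training counts at cut-off ``x``::

    f(x) = FN(x) / (FN(x) + (P/N) * FP(x))

with ``FN(x)`` the positives at or below ``x`` and ``FP(x)`` the negatives
above ``x`` (in oriented values, where "higher" always means "more like
the positive class"). The ``P/N`` factor rescales the negative class to
the size of the positive class, so imbalance does not bias the score.
Values above 0.5 vote positive.

Each feature carries a *relevance* weight

    R = max(sensitivity + specificity - 1, 0)

— the Youden index, clamped at zero — obtained by classifying the training
subjects with the feature's own fitness at cut-off 0.5. Features are
combined through a category tree: at every node the composite score of a
subject is the relevance-weighted mean of the observed children,

    DSI = sum_i R_i f_i / sum_i R_i ,

with missing children simply skipped and the weights renormalised, which
is what lets the index tolerate missing data. The same fitness/relevance
construction is applied recursively to each node's composite training
scores until the root yields the final DSI; a subject is classified
positive when DSI > 0.5.

Conventions not fixed by the construction itself (tie side of the counts,
the 0/0 gap value, the orientation tie) are documented on the functions
below and in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .hierarchy import HierarchySpec

__all__ = [
    "FeatureModel",
    "HierarchyNode",
    "fit_feature",
    "fitness",
    "fit_hierarchy",
    "score_subjects",
    "classify",
]


@dataclass
class FeatureModel:
    """Fitted univariate fitness classifier for one feature.

    ``pos_values``/``neg_values`` are the *oriented* (possibly negated)
    sorted training values; ``orientation`` is +1 when higher raw values
    indicate the positive class, -1 otherwise. ``usable`` is False when a
    class had no non-missing training value, in which case the feature is
    inert: relevance 0 and fitness constant 0.5.
    """

    name: str
    pos_values: np.ndarray
    neg_values: np.ndarray
    orientation: int
    P: int
    N: int
    relevance: float
    usable: bool = True

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "orientation": self.orientation,
            "P": self.P,
            "N": self.N,
            "relevance": self.relevance,
            "usable": self.usable,
            "pos_values": [float(v) for v in self.pos_values],
            "neg_values": [float(v) for v in self.neg_values],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureModel":
        return cls(
            name=d["name"],
            pos_values=np.asarray(d["pos_values"], dtype=float),
            neg_values=np.asarray(d["neg_values"], dtype=float),
            orientation=int(d["orientation"]),
            P=int(d["P"]),
            N=int(d["N"]),
            relevance=float(d["relevance"]),
            usable=bool(d["usable"]),
        )


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) + 0.5 P(pos == neg) via midranks."""
    ranks = rankdata(np.concatenate([pos, neg]))
    p, n = len(pos), len(neg)
    return (ranks[:p].sum() - p * (p + 1) / 2) / (p * n)


def fit_feature(pos_values, neg_values, name: str = "") -> FeatureModel:
    """Fit the fitness classifier of one feature from class-wise training values.

    Orientation is chosen from the Mann-Whitney AUC of the raw values: +1
    (higher = positive) when AUC >= 0.5, else -1, in which case values are
    negated internally so the fitness machinery always sees "higher means
    more positive". A mis-oriented tie (AUC exactly 0.5) is inert because
    such a feature earns relevance ~0 anyway.

    A class with zero non-missing values makes the feature unusable:
    relevance 0, fitness constant 0.5, so it vanishes from every composite.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if len(pos) == 0 or len(neg) == 0:
        return FeatureModel(
            name=name,
            pos_values=np.sort(pos),
            neg_values=np.sort(neg),
            orientation=1,
            P=len(pos),
            N=len(neg),
            relevance=0.0,
            usable=False,
        )
    orientation = 1 if _mann_whitney_auc(pos, neg) >= 0.5 else -1
    model = FeatureModel(
        name=name,
        pos_values=np.sort(orientation * pos),
        neg_values=np.sort(orientation * neg),
        orientation=orientation,
        P=len(pos),
        N=len(neg),
        relevance=0.0,
    )
    model.relevance = _relevance_from_scores(
        fitness(model, pos), fitness(model, neg)
    )
    return model


def fitness(model: FeatureModel, x) -> np.ndarray:
    """Evaluate the fitness function at raw values ``x`` (vectorised).

    Counting convention: with oriented values, FN(x) = #{positives <= x}
    and FP(x) = #{negatives > x} — ties sit with the "at or below"
    (negative-vote) side, which makes the function monotone non-decreasing.
    In a gap between the class supports both counts can be zero; the 0/0
    is defined as 0.5, maximally uninformative. Missing inputs propagate
    as NaN, never substituted.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    if not model.usable:
        out[obs] = 0.5
        return out[0] if scalar else out
    xo = model.orientation * x[obs]
    fn = np.searchsorted(model.pos_values, xo, side="right").astype(float)
    fp = model.N - np.searchsorted(model.neg_values, xo, side="right").astype(float)
    den = fn + (model.P / model.N) * fp
    vals = np.where(den > 0, np.divide(fn, den, out=np.full_like(fn, 0.5), where=den > 0), 0.5)
    out[obs] = vals
    return out[0] if scalar else out


def _relevance_from_scores(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Youden index (clamped at 0) of the score>0.5 classifier.

    NaN scores (subjects unscorable at this node) are excluded; an empty
    class after exclusion yields relevance 0.
    """
    pos = pos_scores[~np.isnan(pos_scores)]
    neg = neg_scores[~np.isnan(neg_scores)]
    if len(pos) == 0 or len(neg) == 0:
        return 0.0
    sens = float(np.mean(pos > 0.5))
    spec = float(np.mean(neg <= 0.5))
    return max(sens + spec - 1.0, 0.0)


@dataclass
class HierarchyNode:
    """A fitted node of the classifier tree.

    Leaves carry a :class:`FeatureModel`; internal nodes carry fitted
    children. ``relevance`` is the node's own Youden weight, computed on
    its composite training scores (leaves: on the feature's fitness).
    """

    name: str
    relevance: float
    feature: FeatureModel | None = None
    children: list["HierarchyNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.feature is not None

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "relevance": self.relevance}
        if self.is_leaf:
            d["feature"] = self.feature.to_dict()
        else:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyNode":
        if "feature" in d:
            return cls(
                name=d["name"],
                relevance=float(d["relevance"]),
                feature=FeatureModel.from_dict(d["feature"]),
            )
        return cls(
            name=d["name"],
            relevance=float(d["relevance"]),
            children=[cls.from_dict(c) for c in d["children"]],
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path: str) -> "HierarchyNode":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def top_level_relevances(self) -> dict[str, float]:
        return {c.name: c.relevance for c in self.children} if self.children else {
            self.name: self.relevance
        }


def _combine(child_scores: list[np.ndarray], weights: list[float]) -> np.ndarray:
    """Relevance-weighted mean over observed children; weights renormalised.

    Only children with positive relevance carry weight; a subject with no
    observed positively-weighted child gets a missing composite. (Zero-
    relevance children therefore never move a score, and an all-unusable
    node is missing, matching the missing-data semantics of the index.)
    """
    V = np.column_stack(child_scores)
    w = np.asarray(weights, dtype=float)
    mask = (~np.isnan(V)) & (w > 0)
    Vz = np.where(mask, V, 0.0)
    num = Vz @ w
    den = mask @ w
    out = np.full(V.shape[0], np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _fit_node(
    spec: HierarchySpec, X: pd.DataFrame, y: np.ndarray
) -> tuple[HierarchyNode, np.ndarray]:
    if "feature" in spec:
        f = spec["feature"]
        values = X[f].to_numpy(dtype=float)
        model = fit_feature(values[y == 1], values[y == 0], name=f)
        return (
            HierarchyNode(name=f, relevance=model.relevance, feature=model),
            fitness(model, values),
        )
    fitted, scores = [], []
    for child in spec["children"]:
        node, sc = _fit_node(child, X, y)
        fitted.append(node)
        scores.append(sc)
    composite = _combine(scores, [n.relevance for n in fitted])
    rel = _relevance_from_scores(composite[y == 1], composite[y == 0])
    return HierarchyNode(name=spec["name"], relevance=rel, children=fitted), composite


def fit_hierarchy(X: pd.DataFrame, y, spec: HierarchySpec) -> HierarchyNode:
    """Fit the full classifier tree on training data.

    Parameters
    ----------
    X
        Training feature matrix (NaN = missing), columns covering every
        leaf of ``spec``.
    y
        Binary labels (1 = positive/declining class). Both classes must be
        present.
    """
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("training set must contain both classes")
    root, _ = _fit_node(spec, X, y)
    return root


def _score_node(node: HierarchyNode, X: pd.DataFrame) -> np.ndarray:
    if node.is_leaf:
        return fitness(node.feature, X[node.feature.name].to_numpy(dtype=float))
    scores = [_score_node(c, X) for c in node.children]
    return _combine(scores, [c.relevance for c in node.children])


def score_subjects(root: HierarchyNode, X: pd.DataFrame) -> np.ndarray:
    """DSI of each row of ``X`` in [0, 1]; NaN where no feature is observed."""
    return _score_node(root, X)


def classify(dsi) -> np.ndarray:
    """'positive' iff DSI > 0.5, 'negative' iff DSI <= 0.5, 'undefined' if missing."""
    dsi = np.atleast_1d(np.asarray(dsi, dtype=float))
    out = np.where(dsi > 0.5, "positive", "negative").astype(object)
    out[np.isnan(dsi)] = "undefined"
    return out
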