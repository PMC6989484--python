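"""Feature-hierarchy configuration.

The classifier aggregates per-feature scores through a tree whose leaves
are features and whose internal nodes are categories (cognitive tests,
cardiovascular risk factors, MRI features, ...). The tree is configured as
nested mappings — ``{"name": ..., "children": [...]}`` for categories and
``{"feature": ...}`` for leaves — read from YAML/JSON or built directly
from the sidecar metadata's slash-separated category paths.
"""

from __future__ import annotations

from importlib import resources
from typing import Any

import pandas as pd
import yaml

HierarchySpec = dict[str, Any]


class HierarchyError(ValueError):
    pass


def _validate(node: HierarchySpec) -> None:
    if "feature" in node:
        if not isinstance(node["feature"], str):
            raise HierarchyError(f"leaf feature must be a string: {node}")
        return
    if "name" not in node or "children" not in node:
        raise HierarchyError(f"internal node needs 'name' and 'children': {node}")
    if not node["children"]:
        raise HierarchyError(f"category {node['name']!r} has no children")
    for child in node["children"]:
        _validate(child)


def load_hierarchy(path: str) -> HierarchySpec:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    _validate(spec)
    names = hierarchy_features(spec)
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise HierarchyError(f"features appear more than once: {dupes}")
    return spec


def save_hierarchy(spec: HierarchySpec, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)


def default_hierarchy() -> HierarchySpec:
    """The packaged default tree (top level: age, sex, education, genetics,
    cognitive tests, cardiovascular risk factors, gait, MRI features)."""
    with resources.files("dsidx.data").joinpath("default_hierarchy.yaml").open() as fh:
        spec = yaml.safe_load(fh)
    _validate(spec)
    return spec


def hierarchy_features(node: HierarchySpec) -> list[str]:
    """Leaf feature names in depth-first order."""
    if "feature" in node:
        return [node["feature"]]
    out: list[str] = []
    for child in node["children"]:
        out.extend(hierarchy_features(child))
    return out


def prune_hierarchy(node: HierarchySpec, keep: set[str]) -> HierarchySpec | None:
    """Drop leaves not in ``keep`` and any category left empty; None if nothing survives."""
    if "feature" in node:
        return dict(node) if node["feature"] in keep else None
    children = [c for c in (prune_hierarchy(ch, keep) for ch in node["children"]) if c]
    if not children:
        return None
    return {"name": node["name"], "children": children}


def hierarchy_from_meta(feature_meta: pd.DataFrame, root_name: str = "dsi") -> HierarchySpec:
    """Build the tree implied by the sidecar metadata's category paths.

    A feature with path ``mri/lesions`` becomes a leaf under dsi → mri →
    lesions; a feature whose path equals its own conceptual category (e.g.
    ``age``) becomes a direct child of the root.
    """
    root: HierarchySpec = {"name": root_name, "children": []}

    def child_named(node: HierarchySpec, name: str) -> HierarchySpec:
        for ch in node["children"]:
            if ch.get("name") == name:
                return ch
        ch = {"name": name, "children": []}
        node["children"].append(ch)
        return ch

    for _, row in feature_meta.iterrows():
        parts = [p for p in str(row["category_path"]).split("/") if p]
        node = root
        # a single-feature top-level category (age, sex, education) collapses
        # to a bare leaf at the root rather than a one-child category
        for part in parts if len(parts) > 1 or _shared(feature_meta, parts) else parts[:-1]:
            node = child_named(node, part)
        node["children"].append({"feature": row["feature"]})
    _validate(root)
    return root


def _shared(meta: pd.DataFrame, parts: list[str]) -> bool:
    """True if more than one feature lives at this exact category path."""
    return int((meta["category_path"] == "/".join(parts)).sum()) > 1


def top_level_names(node: HierarchySpec) -> list[str]:
    """Names of the root's children (feature name for bare leaves)."""
    return [ch.get("name", ch.get("feature")) for ch in node["children"]]


#: shorthand used for cumulative feature-set orders
CATEGORY_ALIASES = {
    "ct": "cognitive_tests",
    "cvr": "cardiovascular",
    "gen": "genetics",
    "edu": "education",
    "mri": "mri",
}


def resolve_feature_set(
    names: list[str], cohort_meta: pd.DataFrame, hierarchy: HierarchySpec
) -> list[str]:
    """Expand a mixed list of feature names / category names / aliases into
    concrete feature names, preserving hierarchy (depth-first) order."""
    wanted: set[str] = set()
    features = set(cohort_meta["feature"])
    for raw in names:
        if raw == "all":
            wanted.update(features)
            continue
        if raw == "all_but_age":
            wanted.update(features - {"age"})
            continue
        name = CATEGORY_ALIASES.get(raw, raw)
        if name in features:
            wanted.add(name)
            continue
        paths = cohort_meta["category_path"].astype(str)
        hit = (paths == name) | paths.str.startswith(name + "/") | paths.str.contains(
            "(?:^|/)" + name + "(?:/|$)", regex=True
        )
        members = list(cohort_meta.loc[hit, "feature"])
        if not members:
            raise HierarchyError(f"unknown feature or category {raw!r}")
        wanted.update(members)
    ordered = [f for f in hierarchy_features(hierarchy) if f in wanted]
    # features outside the configured hierarchy keep metadata order
    ordered += [f for f in cohort_meta["feature"] if f in wanted and f not in ordered]
    return ordered
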