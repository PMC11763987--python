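"""Iterative decision-tree feature selection over dihedral angle columns.

Each round fits a single CART tree (Gini impurity) on the not-yet-selected
angle columns against the class column and records the distinct split
variables; those angles are removed from the feature set before the next
round.  A tree is first grown without size constraints; only if it cannot
separate the classes perfectly is it refit with the leaf constraints
(<= ``max_leaf_nodes`` leaves, every leaf >= ``min_leaf_fraction`` of the
samples).  Both phases apply a minimum impurity decrease per split so that a
round reports only angles whose splits carry real class signal instead of
memorising individual noisy structures; see docs/methods.md for the
rationale and calibration of the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .features import ANGLE_COLUMNS, CLASS_COLUMN

DEFAULT_MAX_LEAF_NODES = 10
DEFAULT_MIN_LEAF_FRACTION = 0.03
DEFAULT_MIN_IMPURITY_DECREASE = 1e-3


@dataclass
class SelectionRound:
    """Result of one feature-selection round."""

    round_index: int  # 1-based
    selected_angles: tuple[str, ...]  # distinct split variables, tree order
    perfectly_separable: bool
    tree: DecisionTreeClassifier
    feature_names: tuple[str, ...]  # columns the tree was fit on

    def summary(self) -> pd.DataFrame:
        """Per-node table: split variable, threshold, Gini impurity, fraction
        of samples reaching the node and the class repartition."""
        t = self.tree.tree_
        total = t.n_node_samples[0]
        rows = []
        for node in range(t.node_count):
            is_leaf = t.children_left[node] == -1
            value = t.value[node].ravel()
            rows.append(
                {
                    "node": node,
                    "split_variable": (
                        None if is_leaf else self.feature_names[t.feature[node]]
                    ),
                    "threshold": None if is_leaf else float(t.threshold[node]),
                    "gini": float(t.impurity[node]),
                    "sample_fraction": t.n_node_samples[node] / total,
                    "class_repartition": np.round(value / value.sum(), 4).tolist(),
                }
            )
        return pd.DataFrame(rows).set_index("node")


def _angles_in_tree_order(
    tree: DecisionTreeClassifier, feature_names: tuple[str, ...]
) -> tuple[str, ...]:
    """Distinct split variables in preorder traversal order."""
    t = tree.tree_
    seen: list[str] = []

    def visit(node: int) -> None:
        if t.children_left[node] == -1:
            return
        name = feature_names[t.feature[node]]
        if name not in seen:
            seen.append(name)
        visit(t.children_left[node])
        visit(t.children_right[node])

    visit(0)
    return tuple(seen)


def fit_selection_round(
    matrix: pd.DataFrame,
    excluded: frozenset[str] | set[str] = frozenset(),
    round_index: int = 1,
    seed: int = 0,
    max_leaf_nodes: int = DEFAULT_MAX_LEAF_NODES,
    min_leaf_fraction: float = DEFAULT_MIN_LEAF_FRACTION,
    min_impurity_decrease: float = DEFAULT_MIN_IMPURITY_DECREASE,
) -> SelectionRound:
    """Fit one selection round on the non-excluded angle columns.

    Raises
    ------
    ValueError
        If every angle column is excluded, or the matrix still contains
        missing values.
    """
    features = tuple(c for c in ANGLE_COLUMNS if c not in excluded)
    if not features:
        raise ValueError("all angle columns are excluded")
    x = matrix[list(features)].to_numpy()
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; impute first")
    y = matrix[CLASS_COLUMN].to_numpy()

    unconstrained = DecisionTreeClassifier(
        criterion="gini",
        random_state=seed,
        min_impurity_decrease=min_impurity_decrease,
    ).fit(x, y)
    if unconstrained.score(x, y) == 1.0:
        tree = unconstrained
        separable = True
    else:
        tree = DecisionTreeClassifier(
            criterion="gini",
            random_state=seed,
            max_leaf_nodes=max_leaf_nodes,
            min_samples_leaf=min_leaf_fraction,
            min_impurity_decrease=min_impurity_decrease,
        ).fit(x, y)
        separable = False
    return SelectionRound(
        round_index=round_index,
        selected_angles=_angles_in_tree_order(tree, features),
        perfectly_separable=separable,
        tree=tree,
        feature_names=features,
    )


def iterate_selection(
    matrix: pd.DataFrame, n_rounds: int = 3, seed: int = 0, **kwargs
) -> list[SelectionRound]:
    """Run ``n_rounds`` selection rounds, removing each round's selected
    angles from the feature set of all later rounds."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rounds: list[SelectionRound] = []
    excluded: set[str] = set()
    for k in range(1, n_rounds + 1):
        rnd = fit_selection_round(
            matrix, excluded=frozenset(excluded), round_index=k, seed=seed, **kwargs
        )
        rounds.append(rnd)
        excluded |= set(rnd.selected_angles)
    return rounds


def selection_report(rounds: list[SelectionRound]) -> pd.DataFrame:
    """Flat CSV-ready report: one row per split node across all rounds."""
    frames = []
    for rnd in rounds:
        summ = rnd.summary().reset_index()
        summ = summ[summ["split_variable"].notna()].copy()
        summ.insert(0, "round", rnd.round_index)
        frames.append(summ)
    if not frames:
        return pd.DataFrame(
            columns=["round", "node", "split_variable", "threshold", "gini",
                     "sample_fraction", "class_repartition"]
        )
    return pd.concat(frames, ignore_index=True)
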