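"""Random-forest variant classification with leave-one-variant-out
cross-validation, the accuracy table over selection-round feature subsets,
and the window-based stability check.

Accuracy is reported at variant granularity: all structures of the held-out
variant are predicted by a forest trained on the structures of every other
variant, and the variant-level call is the majority vote over its structure
predictions (ties broken by the fixed class order, with a warning).
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import ANGLE_COLUMNS, CLASS_COLUMN, VARIANT_COLUMN
from .selection import SelectionRound, iterate_selection
from .variants import CLASS_ORDER

DEFAULT_N_TREES = 5000
#: Round-index subsets reported in the accuracy table.
DEFAULT_SUBSETS: tuple[tuple[int, ...], ...] = ((1, 2), (1, 2, 3), (1, 3), (2, 3), (3,))


@dataclass
class LooResult:
    """Leave-one-variant-out cross-validation result."""

    per_variant: pd.DataFrame  # variant, true/predicted class, correct, votes
    per_structure: pd.DataFrame  # index (variant, trajectory, frame), predicted
    accuracy: float  # % of variants called correctly
    features: tuple[str, ...]
    n_trees: int
    seed: int

    def summary(self) -> pd.DataFrame:
        return self.per_variant


def _majority_vote(predictions: np.ndarray, variant: str) -> str:
    counts = Counter(predictions.tolist())
    top = max(counts.values())
    winners = [c for c, k in counts.items() if k == top]
    if len(winners) > 1:
        warnings.warn(
            f"variant {variant!r}: majority vote tied between {sorted(winners)}; "
            "breaking by class order",
            stacklevel=3,
        )
        winners.sort(key=CLASS_ORDER.index)
    return winners[0]


def loo_variant_cv(
    matrix: pd.DataFrame,
    features: tuple[str, ...] | list[str],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> LooResult:
    """Leave-one-variant-out random-forest cross-validation.

    For each variant a fresh forest (``n_trees`` trees, Gini impurity,
    sqrt(p) features per split, bootstrap, unlimited depth) is trained on all
    structures of the remaining variants and predicts every held-out
    structure; the variant-level call is the majority vote.

    Returns a :class:`LooResult`; ``accuracy`` is the percentage of variants
    whose call matches their true class.
    """
    features = tuple(features)
    unknown = [f for f in features if f not in ANGLE_COLUMNS or f not in matrix.columns]
    if unknown:
        raise ValueError(f"features not in matrix: {unknown}")
    if not features:
        raise ValueError("empty feature set")
    variants = list(dict.fromkeys(matrix[VARIANT_COLUMN]))
    if len(variants) < 2:
        raise ValueError("need at least two variants for leave-one-out CV")
    x_all = matrix[list(features)].to_numpy()
    if np.isnan(x_all).any():
        raise ValueError("matrix contains missing values; impute first")
    y_all = matrix[CLASS_COLUMN].to_numpy()
    var_col = matrix[VARIANT_COLUMN].to_numpy()

    rows = []
    struct_frames = []
    for variant in variants:
        held = var_col == variant
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            criterion="gini",
            max_features="sqrt",
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        ).fit(x_all[~held], y_all[~held])
        preds = forest.predict(x_all[held])
        call = _majority_vote(preds, variant)
        true = y_all[held][0]
        rows.append(
            {
                "variant": variant,
                "true_class": true,
                "predicted_class": call,
                "correct": call == true,
                "n_structures": int(held.sum()),
                "vote_fraction": float(np.mean(preds == call)),
            }
        )
        struct_frames.append(
            pd.DataFrame({"predicted": preds}, index=matrix.index[held])
        )
    per_variant = pd.DataFrame(rows).set_index("variant")
    accuracy = 100.0 * per_variant["correct"].mean()
    return LooResult(
        per_variant=per_variant,
        per_structure=pd.concat(struct_frames),
        accuracy=float(accuracy),
        features=features,
        n_trees=n_trees,
        seed=seed,
    )


def accuracy_table(
    matrix: pd.DataFrame,
    rounds: list[SelectionRound],
    subsets: tuple[tuple[int, ...], ...] = DEFAULT_SUBSETS,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy over feature subsets formed from selection-round unions.

    One row per round-index subset: the feature list (union of the rounds'
    selected angles, round order preserved), the contributing rounds, and the
    leave-one-variant-out accuracy.  Duplicate subsets are dropped (first
    occurrence kept); subsets with an empty feature union are skipped with a
    warning.
    """
    by_index = {r.round_index: r for r in rounds}
    seen: set[tuple[int, ...]] = set()
    rows = []
    for subset in subsets:
        key = tuple(sorted(subset))
        if key in seen:
            continue
        seen.add(key)
        missing = [k for k in subset if k not in by_index]
        if missing:
            warnings.warn(f"skipping subset {subset}: unknown rounds {missing}",
                          stacklevel=2)
            continue
        feats = tuple(
            dict.fromkeys(
                itertools.chain.from_iterable(
                    by_index[k].selected_angles for k in subset
                )
            )
        )
        if not feats:
            warnings.warn(
                f"skipping subset {subset}: empty feature union", stacklevel=2
            )
            continue
        result = loo_variant_cv(matrix, feats, n_trees=n_trees, seed=seed)
        rows.append(
            {
                "features": ", ".join(feats),
                "decision_trees": ", ".join(str(k) for k in subset),
                "accuracy_percent": result.accuracy,
            }
        )
    return pd.DataFrame(rows, columns=["features", "decision_trees", "accuracy_percent"])


@dataclass
class StabilityReport:
    per_window: pd.DataFrame  # window, selected angles, accuracy
    pairwise: pd.DataFrame  # window_a, window_b, jaccard


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def window_stability(
    matrix: pd.DataFrame,
    windows: list[tuple[int, int]],
    n_rounds: int = 1,
    n_trees: int = 500,
    seed: int = 0,
    **selection_kwargs,
) -> StabilityReport:
    """Re-run feature selection (and LOO classification on the selected
    angles) on frame windows and compare the selected-angle sets.

    Parameters
    ----------
    matrix : imputed feature matrix with a (variant, trajectory, frame) index.
    windows : list of half-open frame ranges (start, end)
        Applied to the ``frame`` index level within every trajectory.
    n_rounds : int
        Selection rounds per window; the compared sets are the unions over
        rounds.

    Returns
    -------
    StabilityReport with per-window selections/accuracy and the pairwise
    Jaccard similarity of the selected-angle sets.
    """
    frames_level = matrix.index.get_level_values("frame")
    per_rows = []
    selections: list[set[str]] = []
    for w, (start, end) in enumerate(windows):
        mask = (frames_level >= start) & (frames_level < end)
        if not mask.any():
            raise ValueError(f"window {(start, end)} selects no frames")
        sub = matrix.loc[mask]
        rounds = iterate_selection(sub, n_rounds=n_rounds, seed=seed, **selection_kwargs)
        selected = set().union(*(set(r.selected_angles) for r in rounds))
        acc = np.nan
        if selected:
            acc = loo_variant_cv(
                sub, tuple(sorted(selected)), n_trees=n_trees, seed=seed
            ).accuracy
        per_rows.append(
            {
                "window": f"{start}-{end}",
                "selected_angles": ", ".join(sorted(selected)),
                "accuracy_percent": acc,
            }
        )
        selections.append(selected)
    pair_rows = [
        {
            "window_a": per_rows[i]["window"],
            "window_b": per_rows[j]["window"],
            "jaccard": _jaccard(selections[i], selections[j]),
        }
        for i in range(len(windows))
        for j in range(i + 1, len(windows))
    ]
    return StabilityReport(
        per_window=pd.DataFrame(per_rows),
        pairwise=pd.DataFrame(pair_rows, columns=["window_a", "window_b", "jaccard"]),
    )
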