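"""Leave-one-variant-out random-forest classification and stability checks."""

from types import SimpleNamespace

import numpy as np
import pytest

from dihedra.classify import accuracy_table, loo_variant_cv, window_stability
from dihedra.features import CLASS_COLUMN, VARIANT_COLUMN, assemble_matrix, impute_missing
from dihedra.synthetic import EnsembleParams, sample_dihedrals
from dihedra.variants import CLASS_ORDER, default_manifest

FEATURES = ("psi8", "psi20", "phi9", "psi19")


def nearest_class_mean_calls(matrix, features):
    """Oracle classifier: circular nearest-class-mean on the given features,
    evaluated leave-one-variant-out with majority vote."""
    def circ_mean(deg):
        z = np.exp(1j * np.radians(deg)).mean(axis=0)
        return np.angle(z)

    calls = {}
    variants = list(dict.fromkeys(matrix[VARIANT_COLUMN]))
    x = np.radians(matrix[list(features)].to_numpy())
    y = matrix[CLASS_COLUMN].to_numpy()
    var = matrix[VARIANT_COLUMN].to_numpy()
    for v in variants:
        held = var == v
        means = {}
        for cls in CLASS_ORDER:
            rows = x[~held & (y == cls)]
            if len(rows):
                means[cls] = circ_mean(rows)
        dists = {
            cls: np.abs(np.angle(np.exp(1j * (x[held] - mu[None])))).sum(axis=1)
            for cls, mu in means.items()
        }
        stacked = np.stack([dists[c] for c in means], axis=1)
        preds = np.array(list(means))[np.argmin(stacked, axis=1)]
        labels, counts = np.unique(preds, return_counts=True)
        calls[v] = labels[np.argmax(counts)]
    return calls


class TestLoo:
    def test_single_class_always_correct(self, small_matrix):
        m = small_matrix.copy()
        m[CLASS_COLUMN] = "agonist"
        res = loo_variant_cv(m, FEATURES, n_trees=10, seed=0)
        assert res.accuracy == 100.0
        assert (res.per_variant["predicted_class"] == "agonist").all()

    def test_default_design_fully_recovered(self, small_matrix):
        """Classes are separable in the four informative angles: LOO accuracy
        is 100 % and the calls match a circular nearest-class-mean oracle."""
        res = loo_variant_cv(small_matrix, FEATURES, n_trees=200, seed=0)
        assert res.accuracy == 100.0
        oracle = nearest_class_mean_calls(small_matrix, FEATURES)
        for variant, row in res.per_variant.iterrows():
            assert row["predicted_class"] == oracle[variant]

    def test_unknown_feature_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="not in matrix"):
            loo_variant_cv(small_matrix, ("psi8", "chi1"), n_trees=10)

    def test_accuracy_granularity(self, small_matrix):
        res = loo_variant_cv(small_matrix, FEATURES, n_trees=20, seed=3)
        assert res.accuracy in {i * 12.5 for i in range(9)}

    def test_variant_order_invariance(self, small_matrix):
        res1 = loo_variant_cv(small_matrix, FEATURES, n_trees=50, seed=0)
        reordered = small_matrix.iloc[::-1]
        res2 = loo_variant_cv(reordered, FEATURES, n_trees=50, seed=0)
        assert res1.accuracy == res2.accuracy
        for v in res1.per_variant.index:
            assert (
                res1.per_variant.loc[v, "predicted_class"]
                == res2.per_variant.loc[v, "predicted_class"]
            )

    def test_no_signal_at_or_below_majority_rate(self):
        """Features without class signal cannot beat majority-class calling
        in expectation (20 seeds, one-sided check with binomial slack)."""
        specs = default_manifest()
        correct = 0
        total = 0
        for seed in range(20):
            params = EnsembleParams(
                n_trajectories=1, frames_per_trajectory=40, seed=seed
            )
            tabs = [(s.name, s.class_label, sample_dihedrals(s, params)) for s in specs]
            m = impute_missing(assemble_matrix(tabs))
            res = loo_variant_cv(m, ("phi3", "psi14", "phi28"), n_trees=50, seed=seed)
            correct += int(res.per_variant["correct"].sum())
            total += len(res.per_variant)
        majority = 3 / 8
        # one-sided binomial slack at ~3 sigma
        bound = majority + 3 * np.sqrt(majority * (1 - majority) / total)
        assert correct / total <= bound

    def test_forest_size_robustness(self, specs):
        """Variant calls on the default design do not change between a 500-
        and a 5000-tree forest."""
        params = EnsembleParams(n_trajectories=2, frames_per_trajectory=20, seed=21)
        tabs = [(s.name, s.class_label, sample_dihedrals(s, params)) for s in specs]
        m = impute_missing(assemble_matrix(tabs))
        small = loo_variant_cv(m, FEATURES, n_trees=500, seed=0)
        large = loo_variant_cv(m, FEATURES, n_trees=5000, seed=0)
        assert (
            small.per_variant["predicted_class"].tolist()
            == large.per_variant["predicted_class"].tolist()
        )


def _round(idx, angles):
    return SimpleNamespace(round_index=idx, selected_angles=tuple(angles))


class TestAccuracyTable:
    def test_default_subsets_give_five_rows(self, small_matrix):
        rounds = [
            _round(1, ("psi8", "psi20")),
            _round(2, ("phi9", "psi19")),
            _round(3, ("psi4", "psi10")),
        ]
        table = accuracy_table(small_matrix, rounds, n_trees=20, seed=0)
        assert len(table) == 5
        assert list(table.columns) == ["features", "decision_trees", "accuracy_percent"]

    def test_subset_union_and_dedup(self, small_matrix):
        rounds = [_round(1, ("psi8", "psi20")), _round(2, ("phi9", "psi19"))]
        table = accuracy_table(
            small_matrix, rounds, subsets=((1, 2), (2, 1), (1,)), n_trees=20, seed=0
        )
        assert len(table) == 2  # (2,1) is a duplicate of (1,2)
        assert table.iloc[0]["features"] == "psi8, psi20, phi9, psi19"

    def test_empty_feature_subset_skipped(self, small_matrix):
        rounds = [_round(1, ("psi8", "psi20")), _round(2, ())]
        with pytest.warns(UserWarning, match="empty feature union"):
            table = accuracy_table(
                small_matrix, rounds, subsets=((1,), (2,)), n_trees=20, seed=0
            )
        assert len(table) == 1


class TestWindowStability:
    def test_identical_windows_jaccard_one(self, small_matrix):
        report = window_stability(
            small_matrix, [(0, 30), (0, 30)], n_trees=20, seed=0
        )
        assert report.pairwise["jaccard"].tolist() == [1.0]

    def test_window_combinatorics(self, small_matrix):
        report = window_stability(
            small_matrix, [(0, 10), (10, 20), (20, 30)], n_trees=20, seed=0
        )
        assert len(report.per_window) == 3
        assert len(report.pairwise) == 3

    def test_empty_window_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="no frames"):
            window_stability(small_matrix, [(500, 600)], n_trees=10)

    def test_stationary_ensembles_stable_selection(self):
        """Disjoint late windows of a stationary ensemble select similar
        angles: mean pairwise Jaccard of round-1 unions >= 0.5 (10 seeds)."""
        specs = default_manifest()
        jaccards = []
        for seed in range(10):
            params = EnsembleParams(
                n_trajectories=3, frames_per_trajectory=60, seed=seed
            )
            tabs = [
                (s.name, s.class_label, sample_dihedrals(s, params)) for s in specs
            ]
            m = impute_missing(assemble_matrix(tabs))
            report = window_stability(
                m, [(0, 20), (20, 40), (40, 60)], n_rounds=1, n_trees=10, seed=0
            )
            jaccards.append(report.pairwise["jaccard"].mean())
        assert np.mean(jaccards) >= 0.5
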