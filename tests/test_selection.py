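"""Iterative decision-tree feature selection."""

import numpy as np
import pandas as pd
import pytest

from dihedra.features import ANGLE_COLUMNS, CLASS_COLUMN, VARIANT_COLUMN, assemble_matrix, impute_missing
from dihedra.selection import fit_selection_round, iterate_selection, selection_report
from dihedra.synthetic import EnsembleParams, sample_dihedrals
from dihedra.variants import default_manifest

INFORMATIVE = {"psi8", "psi19", "psi20", "phi9"}


def best_split_gain(values, labels):
    """Oracle: best weighted Gini decrease over all thresholds of one column,
    by exhaustive scan of the sorted values."""
    order = np.argsort(values, kind="stable")
    v, y = np.asarray(values)[order], np.asarray(labels)[order]
    classes, y_idx = np.unique(y, return_inverse=True)
    n = len(v)
    onehot = np.zeros((n, len(classes)))
    onehot[np.arange(n), y_idx] = 1
    prefix = np.cumsum(onehot, axis=0)
    total = prefix[-1]

    def gini(counts, m):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = counts / m
        return 1.0 - np.nansum(p * p)

    root = gini(total, n)
    best = 0.0
    for i in range(1, n):
        if v[i] == v[i - 1]:
            continue
        left = prefix[i - 1]
        right = total - left
        g = root - (i / n) * gini(left, i) - ((n - i) / n) * gini(right, n - i)
        best = max(best, g)
    return best


def toy_matrix(rng, n_per_class=60, strong=("psi8", "psi20"), weak=None):
    """Matrix whose class is a noiseless threshold function of the ``strong``
    angle pair.  ``weak`` optionally encodes the classes a second time in an
    XOR-like layout: still perfectly separable, but every single split has a
    strictly lower impurity gain than the strong pair's one-vs-rest splits,
    so the strong pair always wins round 1."""
    classes = (
        ["agonist"] * n_per_class
        + ["low_affinity_antagonist"] * n_per_class
        + ["high_affinity_antagonist"] * n_per_class
    )
    n = len(classes)
    data = pd.DataFrame(
        rng.uniform(-180, 180, size=(n, len(ANGLE_COLUMNS))),
        columns=list(ANGLE_COLUMNS),
    )
    is_ag = np.array([c == "agonist" for c in classes])
    is_low = np.array([c == "low_affinity_antagonist" for c in classes])
    is_high = ~(is_ag | is_low)
    data[strong[0]] = np.where(is_ag, -100.0, 50.0) + rng.normal(0, 1, n)
    data[strong[1]] = np.where(is_low, 100.0, -50.0) + rng.normal(0, 1, n)
    if weak is not None:
        # split the high class across both off-diagonal quadrants
        half = is_high & (np.arange(n) % 2 == 0)
        w0 = np.where(is_ag | half, -50.0, 50.0)
        w1 = np.where(is_ag | (is_high & ~half), -50.0, 50.0)
        data[weak[0]] = w0 + rng.normal(0, 1, n)
        data[weak[1]] = w1 + rng.normal(0, 1, n)
    data[CLASS_COLUMN] = classes
    data[VARIANT_COLUMN] = "toy"
    return data


class TestFitRound:
    def test_threshold_function_recovers_pair(self, rng):
        """Class depends only on psi8/psi20: exactly those are selected, and
        the single-split impurity-scan oracle confirms they dominate."""
        m = toy_matrix(rng)
        rnd = fit_selection_round(m, seed=0)
        assert set(rnd.selected_angles) == {"psi8", "psi20"}
        assert rnd.perfectly_separable
        y = m[CLASS_COLUMN].to_numpy()
        gains = {c: best_split_gain(m[c].to_numpy(), y) for c in ANGLE_COLUMNS}
        top2 = sorted(gains, key=gains.get, reverse=True)[:2]
        assert set(top2) == {"psi8", "psi20"}

    def test_single_class_no_splits(self, rng):
        m = toy_matrix(rng)
        m[CLASS_COLUMN] = "agonist"
        rnd = fit_selection_round(m, seed=0)
        assert rnd.selected_angles == ()
        assert rnd.perfectly_separable

    def test_all_excluded_raises(self, rng):
        with pytest.raises(ValueError):
            fit_selection_round(toy_matrix(rng), excluded=frozenset(ANGLE_COLUMNS))

    def test_unimputed_matrix_rejected(self, rng):
        m = toy_matrix(rng)
        m.loc[m.index[0], "phi3"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            fit_selection_round(m)

    def test_constant_column_ignored(self, rng):
        m = toy_matrix(rng)
        ref = fit_selection_round(m, seed=0).selected_angles
        m2 = m.copy()
        m2["phi30"] = 17.0
        assert fit_selection_round(m2, seed=0).selected_angles == ref

    def test_row_order_invariance(self, rng):
        m = toy_matrix(rng)
        shuffled = m.sample(frac=1.0, random_state=99)
        assert (
            fit_selection_round(m, seed=0).selected_angles
            == fit_selection_round(shuffled, seed=0).selected_angles
        )

    def test_summary_structure(self, rng):
        rnd = fit_selection_round(toy_matrix(rng), seed=0)
        summ = rnd.summary()
        splits = summ[summ["split_variable"].notna()]
        assert set(splits["split_variable"]) == set(rnd.selected_angles)
        assert (summ["sample_fraction"] <= 1.0).all()
        assert summ.loc[0, "sample_fraction"] == 1.0


class TestIterate:
    def test_rounds_disjoint_and_ordered(self, small_matrix):
        rounds = iterate_selection(small_matrix, n_rounds=3, seed=0)
        assert [r.round_index for r in rounds] == [1, 2, 3]
        sets = [set(r.selected_angles) for r in rounds]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (sets[i] & sets[j])

    def test_stronger_pair_selected_first(self, rng):
        """Two independent separating pairs; the strictly stronger pair wins
        round 1 and the weaker pair is picked up in round 2."""
        m = toy_matrix(rng, n_per_class=600, strong=("psi8", "psi20"),
                       weak=("phi9", "psi19"))
        rounds = iterate_selection(m, n_rounds=2, seed=0)
        assert set(rounds[0].selected_angles) == {"psi8", "psi20"}
        assert set(rounds[1].selected_angles) == {"phi9", "psi19"}
        # oracle: after masking the strong pair, the weak pair dominates
        y = m[CLASS_COLUMN].to_numpy()
        masked = [c for c in ANGLE_COLUMNS if c not in ("psi8", "psi20")]
        gains = {c: best_split_gain(m[c].to_numpy(), y) for c in masked}
        assert set(sorted(gains, key=gains.get, reverse=True)[:2]) == {"phi9", "psi19"}

    def test_single_round_equals_fit(self, small_matrix):
        one = iterate_selection(small_matrix, n_rounds=1, seed=0)
        direct = fit_selection_round(small_matrix, excluded=frozenset(), seed=0)
        assert len(one) == 1
        assert one[0].selected_angles == direct.selected_angles

    def test_informative_set_recovered_across_seeds(self):
        """Default design: rounds 1-2 jointly recover the informative angles
        in at least 95 % of seeds."""
        specs = default_manifest()
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            params = EnsembleParams(
                n_trajectories=3, frames_per_trajectory=100, seed=seed
            )
            tabs = [
                (s.name, s.class_label, sample_dihedrals(s, params)) for s in specs
            ]
            matrix = impute_missing(assemble_matrix(tabs))
            rounds = iterate_selection(matrix, n_rounds=2, seed=0)
            union = set(rounds[0].selected_angles) | set(rounds[1].selected_angles)
            hits += union == INFORMATIVE
        assert hits >= 0.95 * n_seeds

    def test_report_lists_all_rounds(self, rng):
        m = toy_matrix(rng, weak=("phi9", "psi19"))
        rounds = iterate_selection(m, n_rounds=2, seed=0)
        rep = selection_report(rounds)
        assert set(rep["round"]) == {1, 2}
        assert set(rep["split_variable"]) == set(
            rounds[0].selected_angles
        ) | set(rounds[1].selected_angles)
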