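"""Rigid seed-and-extend alignment, hit counting and the dot plot."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dihedra.align import (
    PairAlignment,
    align_pair,
    align_representatives,
    candidate_pairs,
    dot_plot,
    filter_alignments,
    hit_table,
)
from dihedra.geometry import kabsch_rmsd


def random_coil(rng, n, step=3.8):
    """Self-avoiding-ish random walk with constant step length."""
    pts = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    for _ in range(n - 1):
        perturbed = direction + rng.normal(scale=0.6, size=3)
        direction = perturbed / np.linalg.norm(perturbed)
        pts.append(pts[-1] + step * direction)
    return np.array(pts)


class TestAlignPair:
    def test_self_alignment_identity(self, rng):
        a = random_coil(rng, 20)
        aln = align_pair(a, a)
        assert aln.correspondences == tuple((i, i) for i in range(1, 21))
        assert aln.rmsd < 1e-9

    def test_embedded_fragment_recovered(self, rng):
        """A 12-residue fragment rigidly embedded at offset 5 is mapped back
        to its source positions; an exhaustive contiguous-window superposition
        oracle confirms offset 5 is optimal."""
        frag = random_coil(rng, 12)
        host = random_coil(np.random.default_rng(77), 25)
        rot = Rotation.random(rng=rng).as_matrix()
        host[5:17] = frag @ rot.T + np.array([30.0, -12.0, 4.0])
        aln = align_pair(host, frag)
        expected = {(5 + k + 1, k + 1) for k in range(12)}
        assert expected <= set(aln.correspondences)
        assert aln.rmsd < 0.5
        # oracle: best contiguous 12-window of the host against the fragment
        window_rmsds = [
            kabsch_rmsd(host[o : o + 12], frag) for o in range(25 - 12 + 1)
        ]
        assert int(np.argmin(window_rmsds)) == 5
        assert min(window_rmsds) < 1e-9

    def test_random_coils_rarely_pass_filter(self):
        """Independently drawn coils align above the 2 A retention filter in
        at least 90 % of seeds."""
        above = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            a = random_coil(rng, 37)
            b = random_coil(rng, 42)
            aln = align_pair(a, b)
            above += aln.rmsd >= 2.0
        assert above >= 0.9 * n_seeds

    def test_symmetry_up_to_transposition(self, rng):
        a = random_coil(rng, 15)
        b = random_coil(rng, 18)
        ab = align_pair(a, b)
        ba = align_pair(b, a)
        assert ab.rmsd == pytest.approx(ba.rmsd, abs=1e-6)
        assert set(ab.correspondences) == {(q, p) for p, q in ba.correspondences}

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="fragment length"):
            align_pair(random_coil(rng, 4), random_coil(rng, 10), frag_len=5)

    def test_monotone_output(self, rng):
        aln = align_pair(random_coil(rng, 30), random_coil(rng, 30))
        pairs = aln.correspondences
        assert all(
            p2 > p1 and q2 > q1
            for (p1, q1), (p2, q2) in zip(pairs, pairs[1:])
        )


class TestCombinatorics:
    def test_all_representative_pairs(self, rng):
        reps_a = [random_coil(rng, 10) for _ in range(4)]
        reps_b = [random_coil(rng, 10) for _ in range(7)]
        assert len(candidate_pairs(reps_a, reps_b)) == 28
        alns = align_representatives(reps_a, reps_b)
        assert len(alns) == 28
        assert len({a.pair_id for a in alns}) == 28


def _toy_alignment(pair_id, pairs, rmsd):
    return PairAlignment(pair_id=pair_id, correspondences=tuple(pairs), rmsd=rmsd)


class TestFilter:
    def test_strictly_below_threshold(self):
        alns = [
            _toy_alignment("a", [(1, 1)], 1.99),
            _toy_alignment("b", [(1, 1)], 2.0),
            _toy_alignment("c", [(1, 1)], 2.01),
        ]
        kept = filter_alignments(alns, rmsd_max=2.0)
        assert [a.pair_id for a in kept] == ["a"]

    def test_25_of_28_retained(self, rng):
        """28 candidates with 25 below the 2 A threshold keep exactly 25."""
        rmsds = np.concatenate([rng.uniform(0.5, 1.9, 25), [2.0, 2.4, 3.1]])
        rng.shuffle(rmsds)
        alns = [
            _toy_alignment(str(i), [(1, 1)], float(r)) for i, r in enumerate(rmsds)
        ]
        assert len(filter_alignments(alns, 2.0)) == 25

    def test_empty(self):
        assert filter_alignments([], 2.0) == []


class TestHitTable:
    def test_no_alignments(self):
        ht = hit_table([], n_residues=37)
        assert ht.hits.sum() == 0
        assert all(ht.tier(r) == "none" for r in range(1, 38))

    def test_manual_tabulation(self):
        """Alignments covering 1-5, 3-7 and 5-9: hits(5) = 3, hits(1) = 1."""
        alns = [
            _toy_alignment("x", [(p, p) for p in range(1, 6)], 1.0),
            _toy_alignment("y", [(p, p) for p in range(3, 8)], 1.0),
            _toy_alignment("z", [(p, p) for p in range(5, 10)], 1.0),
        ]
        ht = hit_table(alns, n_residues=10)
        assert ht.hits[4] == 3
        assert ht.hits[0] == 1
        # manual oracle for the whole vector
        expected = np.zeros(10, dtype=int)
        for lo, hi in [(1, 5), (3, 7), (5, 9)]:
            expected[lo - 1 : hi] += 1
        np.testing.assert_array_equal(ht.hits, expected)

    def test_constant_hits_no_significance(self):
        alns = [_toy_alignment("x", [(p, p) for p in range(1, 11)], 1.0)]
        ht = hit_table(alns, n_residues=10)
        assert ht.sd == 0.0
        assert ht.residues_in_tier("significant") == frozenset()
        assert ht.residues_in_tier("highly_significant") == frozenset()

    def test_tiers_strict_thresholds(self):
        alns = [
            _toy_alignment(str(i), [(p, p) for p in range(1, k + 1)], 1.0)
            for i, k in enumerate([10, 8, 5, 2, 2])
        ]
        ht = hit_table(alns, n_residues=10)
        table = ht.table()
        for r in range(1, 11):
            h = ht.hits[r - 1]
            expected = (
                "highly_significant" if h > ht.mean + ht.sd
                else "significant" if h > ht.mean
                else "none"
            )
            assert table.loc[r, "tier"] == expected
        assert (table["over_half"] == (ht.hits > 0.5 * 5)).all()

    def test_order_invariance(self, rng):
        alns = [
            _toy_alignment(str(i), [(p, p + 1) for p in range(i + 1, i + 6)], 1.0)
            for i in range(6)
        ]
        fwd = hit_table(alns, n_residues=20)
        rev = hit_table(alns[::-1], n_residues=20)
        np.testing.assert_array_equal(fwd.hits, rev.hits)


class TestDotPlot:
    def test_single_alignment_cells(self):
        aln = _toy_alignment("x", [(1, 2), (3, 4), (5, 6)], 1.0)
        dp = dot_plot([aln], n_a=6, n_b=7)
        assert dp.to_numpy().sum() == 3
        assert dp.loc[1, 2] == dp.loc[3, 4] == dp.loc[5, 6] == 1

    def test_shared_pair_accumulates(self):
        alns = [
            _toy_alignment("x", [(6, 3)], 1.0),
            _toy_alignment("y", [(6, 3)], 1.2),
        ]
        dp = dot_plot(alns, n_a=37, n_b=42)
        assert dp.loc[6, 3] == 2
        assert dp.shape == (37, 42)

    def test_row_sums_equal_hit_counts(self, rng):
        alns = []
        for i in range(5):
            start = int(rng.integers(1, 20))
            alns.append(
                _toy_alignment(
                    str(i),
                    [(start + k, start + k + 2) for k in range(8)],
                    1.0,
                )
            )
        dp = dot_plot(alns, n_a=37, n_b=42)
        ht = hit_table(alns, n_residues=37)
        np.testing.assert_array_equal(dp.sum(axis=1).to_numpy(), ht.hits)
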