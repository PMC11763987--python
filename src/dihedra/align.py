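"""Pairwise rigid structural alignment of cluster representatives, hit-count
tabulation with graded significance, and the residue-correspondence dot plot.

The built-in aligner is a rigid seed-and-extend procedure: every contiguous
fragment pair of length ``frag_len`` seeds a Kabsch superposition, the
correspondence is greedily extended with sequential residue pairs whose
post-superposition C-alpha distance is below ``extend_cutoff``, the
superposition is refined on the extended correspondence, and the procedure
iterates to convergence.  The converged correspondence is then completed to a
near-global one by filling the remaining monotone gaps without a distance
restriction (complete-peptide semantics: the reported RMSD measures overall
agreement, so dissimilar structures fail a 2 A filter instead of sneaking
through on a short local match).  Among all seeds, the longest correspondence
wins, with lower RMSD breaking ties.  Flexible (twist-allowing) alignment is
out of scope; externally computed correspondences can be supplied through
:func:`dihedra.io.read_alignment_imports` instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import kabsch_rmsd, kabsch_rmsd_batch, kabsch_rotation
from .synthetic import Conformation


@dataclass(frozen=True)
class PairAlignment:
    """A monotone residue correspondence between two structures."""

    pair_id: str
    correspondences: tuple[tuple[int, int], ...]  # 1-based (pos A, pos B)
    rmsd: float
    source: str = "internal"

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")
        prev = None
        for pa, pb in self.correspondences:
            if prev is not None and not (pa > prev[0] and pb > prev[1]):
                raise ValueError("correspondences must be strictly increasing")
            prev = (pa, pb)

    def __len__(self) -> int:
        return len(self.correspondences)


@dataclass
class HitTable:
    """Per-residue alignment hit counts with graded significance tiers."""

    hits: np.ndarray  # length n_residues, counts
    mean: float
    sd: float
    n_alignments: int

    def tier(self, residue: int) -> str:
        h = self.hits[residue - 1]
        if h > self.mean + self.sd:
            return "highly_significant"
        if h > self.mean:
            return "significant"
        return "none"

    def residues_in_tier(self, tier: str) -> frozenset[int]:
        return frozenset(
            r for r in range(1, len(self.hits) + 1) if self.tier(r) == tier
        )

    def table(self) -> pd.DataFrame:
        n = len(self.hits)
        over50 = self.hits > 0.5 * self.n_alignments
        return pd.DataFrame(
            {
                "residue": np.arange(1, n + 1),
                "hits": self.hits,
                "tier": [self.tier(r) for r in range(1, n + 1)],
                "over_half": over50,
            }
        ).set_index("residue")


def _monotone_chain(candidates: np.ndarray, dists: np.ndarray) -> list[int]:
    """Longest strictly increasing chain over (i, j) index pairs, ties broken
    by smaller total distance.  O(k^2) dynamic program."""
    order = np.lexsort((candidates[:, 1], candidates[:, 0]))
    cand = candidates[order]
    d = dists[order]
    k = len(cand)
    best_len = np.ones(k, dtype=int)
    best_cost = d.copy()
    parent = np.full(k, -1)
    for t in range(k):
        prev = np.nonzero(
            (cand[:t, 0] < cand[t, 0]) & (cand[:t, 1] < cand[t, 1])
        )[0]
        if len(prev) == 0:
            continue
        lens = best_len[prev]
        top = lens.max()
        tied = prev[lens == top]
        pick = tied[np.argmin(best_cost[tied])]
        best_len[t] = top + 1
        best_cost[t] = best_cost[pick] + d[t]
        parent[t] = pick
    end = int(np.lexsort((best_cost, -best_len))[0])
    chain = []
    while end != -1:
        chain.append(end)
        end = parent[end]
    chain.reverse()
    return [int(order[c]) for c in chain]


def _fill_gaps(
    corr: list[tuple[int, int]],
    dmat: np.ndarray,
    cutoff: float,
    na: int,
    nb: int,
) -> list[tuple[int, int]]:
    """Insert the best monotone chains of close residue pairs into the gaps
    of an existing correspondence (existing pairs are never removed)."""
    bounds = [(-1, -1)] + corr + [(na, nb)]
    out: list[tuple[int, int]] = []
    for (p1, q1), (p2, q2) in zip(bounds, bounds[1:]):
        if p2 - p1 > 1 and q2 - q1 > 1:
            sub = dmat[p1 + 1 : p2, q1 + 1 : q2]
            ci, cj = np.nonzero(sub < cutoff)
            if len(ci):
                cand = np.stack([ci, cj], axis=1)
                chain = _monotone_chain(cand, sub[ci, cj])
                out.extend(
                    (int(cand[c, 0]) + p1 + 1, int(cand[c, 1]) + q1 + 1)
                    for c in chain
                )
        if (p2, q2) != (na, nb):
            out.append((p2, q2))
    return out


def align_pair(
    a: Conformation | np.ndarray,
    b: Conformation | np.ndarray,
    frag_len: int = 5,
    extend_cutoff: float = 3.0,
    pair_id: str = "",
    top_seeds: int = 20,
    max_iter: int = 20,
) -> PairAlignment:
    """Rigidly align two structures on C-alpha coordinates.

    Parameters
    ----------
    a, b : Conformation or (n, 3) C-alpha coordinate arrays.
    frag_len : int
        Seed fragment length.
    extend_cutoff : float
        Distance threshold (Angstrom) for adding residue pairs during
        extension.
    top_seeds : int
        Number of best-scoring seed superpositions carried into the
        extension phase (all contiguous fragment pairs are scored).

    Returns
    -------
    PairAlignment with 1-based positions and the final superposition RMSD
    over the aligned C-alpha pairs.
    """
    ca_a = a.ca if isinstance(a, Conformation) else np.asarray(a, dtype=float)
    ca_b = b.ca if isinstance(b, Conformation) else np.asarray(b, dtype=float)
    na, nb = len(ca_a), len(ca_b)
    if na == 0 or nb == 0:
        raise ValueError("cannot align empty structures")
    if na < frag_len or nb < frag_len:
        raise ValueError(
            f"structures shorter than the seed fragment length {frag_len}"
        )

    # score all contiguous fragment pairs with batched Kabsch
    ia = np.arange(na - frag_len + 1)
    ib = np.arange(nb - frag_len + 1)
    frag_a = np.stack([ca_a[i : i + frag_len] for i in ia])
    frag_b = np.stack([ca_b[j : j + frag_len] for j in ib])
    gi, gj = np.meshgrid(ia, ib, indexing="ij")
    seed_rmsd = kabsch_rmsd_batch(
        frag_a[:, None].repeat(len(ib), axis=1).reshape(-1, frag_len, 3),
        frag_b[None, :].repeat(len(ia), axis=0).reshape(-1, frag_len, 3),
    )
    flat = np.argsort(seed_rmsd, kind="stable")[:top_seeds]

    best: tuple[int, float, list[tuple[int, int]]] | None = None
    for s in flat:
        i0, j0 = int(gi.ravel()[s]), int(gj.ravel()[s])
        corr = [(i0 + k, j0 + k) for k in range(frag_len)]
        for _ in range(max_iter):
            pa = ca_a[[p for p, _ in corr]]
            pb = ca_b[[q for _, q in corr]]
            r, t = kabsch_rotation(pb, pa)
            moved = ca_b @ r.T + t
            dmat = np.linalg.norm(ca_a[:, None, :] - moved[None, :, :], axis=2)
            # growth-only extension: pairs already in the correspondence are
            # kept; the monotone gaps between them are filled with the best
            # chains of residue pairs inside the distance cutoff
            new_corr = _fill_gaps(corr, dmat, extend_cutoff, na, nb)
            if new_corr == corr:
                break
            corr = new_corr
        # complete-peptide semantics: after the close-pair extension has
        # converged, fill the remaining monotone gaps without a distance
        # restriction so the reported RMSD measures global agreement, not
        # just the best local patch
        pa = ca_a[[p for p, _ in corr]]
        pb = ca_b[[q for _, q in corr]]
        r, t = kabsch_rotation(pb, pa)
        moved = ca_b @ r.T + t
        dmat = np.linalg.norm(ca_a[:, None, :] - moved[None, :, :], axis=2)
        corr = _fill_gaps(corr, dmat, np.inf, na, nb)
        pa = ca_a[[p for p, _ in corr]]
        pb = ca_b[[q for _, q in corr]]
        rmsd = kabsch_rmsd(pa, pb)
        key = (len(corr), -rmsd)
        if best is None or key > (best[0], -best[1]):
            best = (len(corr), rmsd, corr)
    assert best is not None
    _, rmsd, corr = best
    return PairAlignment(
        pair_id=pair_id,
        correspondences=tuple((p + 1, q + 1) for p, q in corr),
        rmsd=rmsd,
        source="internal",
    )


def candidate_pairs(reps_a: list, reps_b: list) -> list[tuple[int, int]]:
    """All representative index pairs between two ensembles (the candidate
    alignments before any RMSD filtering)."""
    return [(i, j) for i in range(len(reps_a)) for j in range(len(reps_b))]


def align_representatives(
    confs_a: list[Conformation],
    confs_b: list[Conformation],
    frag_len: int = 5,
    extend_cutoff: float = 3.0,
) -> list[PairAlignment]:
    """Align every representative of ensemble A against every representative
    of ensemble B (len(A) x len(B) candidate alignments)."""
    out = []
    for i, j in candidate_pairs(confs_a, confs_b):
        out.append(
            align_pair(
                confs_a[i],
                confs_b[j],
                frag_len=frag_len,
                extend_cutoff=extend_cutoff,
                pair_id=f"{i}-{j}",
            )
        )
    return out


def filter_alignments(
    alignments: list[PairAlignment], rmsd_max: float = 2.0
) -> list[PairAlignment]:
    """Keep alignments with RMSD strictly below ``rmsd_max``, preserving
    order."""
    return [a for a in alignments if a.rmsd < rmsd_max]


def hit_table(alignments: list[PairAlignment], n_residues: int = 37) -> HitTable:
    """Count, per residue of structure A, how many alignments include it.

    Mean and (population) standard deviation are taken over the per-residue
    counts; tiers use strict inequalities: hits > mean is ``significant``,
    hits > mean + sd is ``highly_significant``.
    """
    hits = np.zeros(n_residues, dtype=int)
    for aln in alignments:
        for pa, _ in aln.correspondences:
            if pa < 1 or pa > n_residues:
                raise ValueError(f"position {pa} outside 1..{n_residues}")
            hits[pa - 1] += 1
    mean = float(hits.mean()) if n_residues else 0.0
    sd = float(hits.std(ddof=0)) if n_residues else 0.0
    return HitTable(hits=hits, mean=mean, sd=sd, n_alignments=len(alignments))


def dot_plot(
    alignments: list[PairAlignment], n_a: int = 37, n_b: int = 42
) -> pd.DataFrame:
    """Correspondence-count matrix: rows are structure-A residues (1..n_a),
    columns structure-B residues (1..n_b)."""
    counts = np.zeros((n_a, n_b), dtype=int)
    for aln in alignments:
        for pa, pb in aln.correspondences:
            if not (1 <= pa <= n_a and 1 <= pb <= n_b):
                raise ValueError(f"pair ({pa}, {pb}) outside the matrix bounds")
            counts[pa - 1, pb - 1] += 1
    return pd.DataFrame(
        counts,
        index=pd.RangeIndex(1, n_a + 1, name="residue_a"),
        columns=pd.RangeIndex(1, n_b + 1, name="residue_b"),
    )
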