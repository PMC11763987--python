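# Methods

This note documents the models, parameters, numerical choices and known
limitations of `dihedra`. All residue positions are 1-based in the 37-residue
reference amylin frame; angle names follow the field convention
(`psi8` = ψ of reference residue 8). All angles are degrees in (−180°, 180°];
coordinates are Å.

## Synthetic conformational ensembles

The generator stands in for enhanced-sampling MD output. For each variant it
draws `n_trajectories × frames_per_trajectory` (default 3 × 1000) independent
frames; every φ/ψ angle of every present residue is sampled from a von Mises
distribution — the maximum-entropy circular analogue of a Gaussian, the
natural choice for torsional noise. Defaults:

| parameter | default | meaning |
|---|---|---|
| `default_concentration` (κ) | 8 | circular spread ≈ 1/√κ rad ≈ 20° |
| `base_phi_mean` / `base_psi_mean` | −100° / 120° | shared coil-like means for non-informative angles |
| informative angles | ψ8, ψ19, ψ20, φ9 | class-dependent means (below) |
| frames | 3 × 1000 | retained-frame layout of the emulated trajectories |

Class means of the informative angles:

| angle | agonist | low-affinity ant. | high-affinity ant. |
|---|---|---|---|
| ψ8  | −130° | 30°  | 30°  |
| ψ19 | 100°  | −80° | −80° |
| ψ20 | −70°  | 100° | −70° |
| φ9  | −60°  | 120° | −60° |

ψ8/ψ19 each separate the agonists from the rest; ψ20/φ9 each separate the
low-affinity antagonists; the high-affinity class is the residual. This
structure was chosen so that (a) every class separation is ≥ 60° (mostly
150–180°, i.e. 7–9 circular standard deviations at κ = 8), (b) any single
selection round needs one angle of each kind, and (c) the pair left after
round 1 still separates all three classes — the informative set is therefore
recovered by two rounds regardless of which angle wins a within-round tie.

The default variant manifest has three agonists (the real human amylin, rat
amylin and pramlintide sequences) and five synthetic full-length antagonist
stand-ins. The antagonists are deliberately *not* deletion variants: imputing
a deleted angle column fills it with a per-column constant that uniquely
identifies the variant, which would leak class signal into nominally
uninformative columns and corrupt the design's contract that only the four
informative angles differ between classes. Deletion variants remain fully
supported (deletion bookkeeping, masking, imputation) for custom manifests.

Backbones are rebuilt from the sampled torsions by sequential
internal-coordinate (NeRF) placement with idealised geometry: bonds
N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles N–Cα–C 111.2°,
Cα–C–N 116.2°, C–N–Cα 121.7°; ω fixed at 180°. The resulting consecutive
Cα–Cα distance is 3.804 Å. Chains carry two cap pseudo-atoms by default — an
acetyl-like carbonyl carbon before residue 1 and an amide-like nitrogen
after the last residue — so φ of the first and ψ of the last residue are
defined, mirroring capped-termini simulation setups; without caps those
angles are reported missing. Caps are written to PDB as single-atom ACE/NH2
residues outside the 3-atoms-per-residue backbone count.

What the generator does *not* emulate: side chains, sterics, secondary
structure propensities, inter-residue correlation, and trajectory
autocorrelation (frames are i.i.d.). Passing tests therefore demonstrate
that the *analysis machinery* recovers a known planted signal under
realistic circular noise — not that real MD ensembles contain such a signal.

## Feature matrix

The matrix has exactly 74 columns: φ1..φ36, ψ1..ψ36, `class`, `variant`;
rows are indexed by (variant, trajectory, frame). Residue 37's angles are
excluded by convention, fixing 72 angle columns for the 37-residue reference
frame. At the reference scale (8 variants × 3 × 1000 frames) the matrix is
24,000 × 74. Assembly keeps the *last* `frames_per_trajectory` frames per
trajectory. Angles of reference positions absent from a deletion variant are
missing; imputation replaces each missing cell with the circular
(resultant-vector) mean of the column's observed values. The circular mean
is used deliberately: the arithmetic mean of {+170°, −170°} is 0°, the
circular mean is the correct 180°. Imputation is idempotent and fails loudly
on a fully missing column.

## Feature selection

Each round fits one CART tree (Gini impurity, scikit-learn) on the
not-yet-selected angle columns; the round's selection is the distinct split
variables in preorder. Two-phase fitting: an unconstrained tree first; if it
does not reach 100 % training accuracy it is refit with ≤ 10 leaf nodes and
a 3 % minimum leaf fraction. Both phases additionally require a minimum
impurity decrease per split (default 10⁻³). This floor is the package's own
addition and is load-bearing: on continuous noisy data an unconstrained CART
always reaches 100 % training accuracy by memorising straggler structures
with arbitrary (noise) split variables, which would make "angles used by the
tree" meaningless as a selection. At the default scale, genuine
class-separating splits gain ~0.2–0.35 and memorisation splits ≲ 10⁻⁴, so
the floor cleanly separates the two regimes without touching real signal.
Consequence: at very small sample sizes (n ≲ a few hundred) single-point
gains can exceed the floor, so selections are cleanest at the reference
scale. Tie-breaks among equally good splits are fixed by the seeded
scikit-learn feature shuffle, making selection deterministic per seed and
invariant to row order. On the default design round 3 selects nothing (all
signal is removed by rounds 1–2), so the accuracy table skips
round-3-only subsets with a warning.

## Classification

Leave-one-variant-out cross-validation: for each variant, a random forest
(default 5000 trees, Gini, √p features per split, bootstrap, unlimited
depth, fixed seed, single-threaded) is trained on all structures of the
other seven variants and predicts every held-out structure. The variant call
is the majority vote over its structure predictions; ties are broken by the
fixed class order (agonist < low-affinity < high-affinity) with a warning.
Accuracy is reported at variant granularity (multiples of 12.5 % for eight
variants). The vote-aggregation rule and the tie-break are package choices;
with the default design votes are essentially unanimous, and variant calls
are unchanged between 500 and 5000 trees.

The window-stability check re-runs selection (and classification on the
selected angles) on frame windows within each trajectory and reports
pairwise Jaccard similarity of the selected-angle sets — for stationary
ensembles, disjoint late windows select substantially overlapping sets.

## Clustering

Greedy maximum-neighbor (Daura) clustering on the Cα-RMSD metric: at each
step the structure with the most neighbors (RMSD ≤ cutoff, default 2 Å)
among the remaining pool becomes a representative; it and its neighbors are
removed; neighbor counts are recomputed on the shrinking pool. Tie-breaks go
to the lowest structure index. Cluster sizes are non-increasing by
construction. The retention filter keeps clusters holding ≥ 2 % of all
structures (exactly 2 % is kept; strictly below is discarded). Pairwise RMSD
matrices are computed with a batched closed-form Kabsch (SVD with
determinant sign correction, so reflections are never used); the single-pair
routine recomputes RMSD from explicit superposition residuals to avoid
cancellation error near zero.

## Structural alignment

The built-in aligner is rigid (no twists): every contiguous fragment pair
(default length 5) is Kabsch-superposed; the best-scoring seeds (default 20)
are extended by repeatedly superposing on the current correspondence and
filling its monotone gaps with residue pairs closer than `extend_cutoff`
(default 3 Å), pairs once added never being removed; after convergence the
remaining monotone gaps are filled without a distance restriction. The last
step gives the alignment complete-peptide semantics: the reported RMSD
measures *global* agreement, so two unrelated coils (whose best local
5-residue patches superpose well) score far above the 2 Å retention filter,
while genuinely similar structures keep full-length low-RMSD alignments.
Candidate alignments are all representative pairs (4 × 7 retained
representatives ⇒ 28 candidates); the retention filter is a strict
RMSD < 2 Å. Per-residue hits are counted over retained alignments; the
significance tiers use strict inequalities against the mean and the mean
plus one population standard deviation (ddof = 0) of the 37 per-residue
counts, and residues aligned in over half of the retained alignments are
additionally flagged (two conventions coexist in the field; both are
reported). The dot plot accumulates correspondence counts on the
37 × 42 residue grid; its row sums equal the hit counts by construction.

Correspondences computed by external aligners (e.g. flexible ones) can be
imported from a simple TSV dialect (`record/pair_id/a/b` header; `P` rows
for residue pairs, `R` rows for the pair RMSD); converting another tool's
output to this dialect is a few lines of scripting.

## Consensus scoring

Each evidence source contributes an integer weight to every residue it
names: machine learning (residues of the angles selected in rounds 1–2 by
default; configurable) = 2; structural highly-significant tier = 2;
structural significant tier = 1; strong sequence-alignment tier = 2; weak
tier = 1. Totals are linear in the weights; ranking is by descending total
with ties broken by residue index. Report A sums simulation-derived sources
only; report B adds the sequence tiers. Sequence-alignment tiers are
consumed as annotations (TSV of residue/tier) rather than recomputed,
because the upstream web service depends on live databases and is not
bit-reproducible.

## Pipeline

Stages communicate only through files under the output directory, so any
stage can be re-run in isolation and synthetic PDB ensembles can be swapped
for real ones. A fixed seed makes the whole run byte-identical (the run
manifest's wall-clock timings excepted). Configuration validation reports
errors (out-of-range parameters, missing paths) before any computation and
warnings for departures from the reference settings (5000 trees, 2 Å
cutoffs, 2 % retention).

## Problem sizes

The test suite exercises the reference scale (24,000 × 74 matrix, 5000-tree
forests) for the headline classification result and scaled-down layouts
(tens of frames per trajectory, hundreds of toy structures) everywhere a
property does not depend on scale; `scripts/acceptance.py` always runs the
reference scale. Stochastic properties (selection recovery, no-signal
accuracy bounds, window stability) are checked over 10–20 seeds at reduced
depth.

## Known limitations

- The generator's i.i.d. frames ignore trajectory autocorrelation, so the
  window-stability check is easier to pass synthetically than on real MD.
- CART thresholds act on raw degree values; the wrap at ±180° is ignored
  (a class whose mean sits near ±180° can be split into two intervals).
  The default design keeps informative means away from the wrap.
- The rigid aligner is a desk-scale substitute for flexible structural
  alignment; twist-requiring similarities will score poorly. Import real
  correspondences for such cases.
- Representative-selection ties in clustering depend on structure indices;
  partitions are order-invariant but representative identity within an
  exactly tied cluster is not.
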