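"""Cumulative per-residue consensus scoring.

Evidence from the machine-learning feature selection, the structural-alignment
hit tiers and (optionally) sequence-alignment tiers is combined into one
integer score per reference residue: each evidence source contributes its
weight to every residue it contains, and residues are ranked by the total.
Default weights: ML = 2, structural highly-significant tier = 2, structural
significant tier = 1, strong sequence tier = 2, weak sequence tier = 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .align import HitTable
from .selection import SelectionRound
from .variants import REFERENCE_LENGTH

ML_SOURCE = "ml"
STRUCTURAL_TIER2 = "structural_tier2"  # hits > mean + sd
STRUCTURAL_TIER1 = "structural_tier1"  # mean < hits <= mean + sd
COBALT_STRONG = "cobalt_strong"
COBALT_WEAK = "cobalt_weak"

DEFAULT_WEIGHTS = {
    ML_SOURCE: 2,
    STRUCTURAL_TIER2: 2,
    STRUCTURAL_TIER1: 1,
    COBALT_STRONG: 2,
    COBALT_WEAK: 1,
}
#: Sources derived from the simulation data alone (consensus report A);
#: report B adds the sequence-homology sources.
SIMULATION_SOURCES = (ML_SOURCE, STRUCTURAL_TIER2, STRUCTURAL_TIER1)

_ANGLE_RE = re.compile(r"^(phi|psi)(\d+)$")


@dataclass(frozen=True)
class EvidenceSource:
    """A named set of residues contributing ``weight`` points each."""

    name: str
    residues: frozenset[int]
    weight: int

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        bad = [r for r in self.residues if r < 1 or r > REFERENCE_LENGTH]
        if bad:
            raise ValueError(f"residues outside 1..{REFERENCE_LENGTH}: {sorted(bad)}")


@dataclass
class ConsensusTable:
    """Per-residue contributions and totals."""

    table: pd.DataFrame  # index residue 1..37; one column per source + total

    @property
    def totals(self) -> pd.Series:
        return self.table["total"]

    def ranking(self) -> pd.DataFrame:
        """Residues sorted by descending total, ties broken by residue index."""
        out = self.table.sort_values(
            ["total"], ascending=False, kind="stable"
        ).copy()
        out["rank"] = out["total"].rank(method="dense", ascending=False).astype(int)
        return out


def ml_residues(
    rounds: list[SelectionRound], use_rounds: tuple[int, ...] = (1, 2)
) -> frozenset[int]:
    """Residue indices named by the selected angles of the designated rounds
    (``psi8`` maps to residue 8; phi and psi of one residue count once)."""
    out: set[int] = set()
    for rnd in rounds:
        if rnd.round_index not in use_rounds:
            continue
        for angle in rnd.selected_angles:
            m = _ANGLE_RE.match(angle)
            if not m:
                raise ValueError(f"unrecognised angle name {angle!r}")
            out.add(int(m.group(2)))
    return frozenset(out)


def structural_sources(
    ht: HitTable, weights: dict[str, int] = DEFAULT_WEIGHTS
) -> list[EvidenceSource]:
    """Evidence sources from the hit-table significance tiers."""
    return [
        EvidenceSource(
            STRUCTURAL_TIER2,
            ht.residues_in_tier("highly_significant"),
            weights[STRUCTURAL_TIER2],
        ),
        EvidenceSource(
            STRUCTURAL_TIER1,
            ht.residues_in_tier("significant"),
            weights[STRUCTURAL_TIER1],
        ),
    ]


def score_residues(sources: list[EvidenceSource]) -> ConsensusTable:
    """Sum the per-source contributions into the cumulative residue score."""
    names = [s.name for s in sources]
    if len(set(names)) != len(names):
        raise ValueError("duplicate evidence source names")
    idx = pd.RangeIndex(1, REFERENCE_LENGTH + 1, name="residue")
    table = pd.DataFrame(0, index=idx, columns=names, dtype=int)
    for s in sources:
        table.loc[sorted(s.residues), s.name] = s.weight
    table["total"] = table[names].sum(axis=1)
    return ConsensusTable(table=table)


def split_reports(
    table: ConsensusTable, sources: list[EvidenceSource]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Report A: totals over simulation-derived sources only; report B: all
    sources.  Per-residue totals in B are always >= those in A."""
    sim_names = [s.name for s in sources if s.name in SIMULATION_SOURCES]
    all_names = [s.name for s in sources]
    a = table.table[sim_names].copy()
    a["total"] = a.sum(axis=1)
    b = table.table[all_names].copy()
    b["total"] = b.sum(axis=1)
    return a, b


def read_sequence_tiers(path, weights: dict[str, int] = DEFAULT_WEIGHTS) -> list[EvidenceSource]:
    """Read sequence-alignment tier annotations from a TSV file with columns
    ``residue`` and ``tier`` (``strong`` or ``weak``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"residue", "tier"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'residue' and 'tier'")
    strong = frozenset(int(r) for r in df.loc[df["tier"] == "strong", "residue"])
    weak = frozenset(int(r) for r in df.loc[df["tier"] == "weak", "residue"])
    unknown = set(df["tier"]) - {"strong", "weak"}
    if unknown:
        raise ValueError(f"{path}: unknown tiers {sorted(unknown)}")
    return [
        EvidenceSource(COBALT_STRONG, strong, weights[COBALT_STRONG]),
        EvidenceSource(COBALT_WEAK, weak, weights[COBALT_WEAK]),
    ]
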