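"""Peptide variant specifications and the default variant manifest.

All residue positions in this package are 1-based indices into the 37-residue
reference amylin frame, counted from the N-terminus.  A deletion variant keeps
the reference numbering of its remaining residues, so angle names such as
``psi8`` always mean "psi of reference residue 8" regardless of variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REFERENCE_LENGTH = 37

AGONIST = "agonist"
LOW_AFFINITY = "low_affinity_antagonist"
HIGH_AFFINITY = "high_affinity_antagonist"
#: Fixed class ordering, also the tie-break order for majority votes.
CLASS_ORDER = (AGONIST, LOW_AFFINITY, HIGH_AFFINITY)

HUMAN_AMYLIN = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"
RAT_AMYLIN = "KCNTATCATQRLANFLVRSSNNLGPVLPPTNVGSNTY"
PRAMLINTIDE = "KCNTATCATQRLANFLVHSSNNFGPILPPTNVGSNTY"

#: Reference amyloid beta 1-42 sequence, used as the structural-alignment
#: partner peptide (its N-terminal residues 1-10 form the signaling domain).
AMYLOID_BETA_42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"


class ManifestError(ValueError):
    """Raised for inconsistent variant definitions."""


@dataclass(frozen=True)
class VariantSpec:
    """One peptide variant of the reference amylin frame.

    Parameters
    ----------
    name : str
        Short identifier.
    sequence : str
        One-letter residue string of the variant itself (length <= 37).
    class_label : str
        One of ``agonist``, ``low_affinity_antagonist``,
        ``high_affinity_antagonist``.
    deletions : tuple of int
        Reference positions (1-based) absent from this variant.
    """

    name: str
    sequence: str
    class_label: str
    deletions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_ORDER:
            raise ManifestError(
                f"variant {self.name!r}: unknown class label {self.class_label!r}; "
                f"expected one of {CLASS_ORDER}"
            )
        dels = tuple(sorted(set(self.deletions)))
        object.__setattr__(self, "deletions", dels)
        if any(p < 1 or p > REFERENCE_LENGTH for p in dels):
            raise ManifestError(
                f"variant {self.name!r}: deletion positions must lie in "
                f"1..{REFERENCE_LENGTH}"
            )
        if len(self.sequence) != REFERENCE_LENGTH - len(dels):
            raise ManifestError(
                f"variant {self.name!r}: sequence length {len(self.sequence)} "
                f"inconsistent with {len(dels)} deletions from a "
                f"{REFERENCE_LENGTH}-residue reference"
            )
        if not self.sequence:
            raise ManifestError(f"variant {self.name!r}: empty sequence")

    @property
    def present_positions(self) -> tuple[int, ...]:
        """Reference positions present in this variant, in order."""
        return tuple(
            p for p in range(1, REFERENCE_LENGTH + 1) if p not in self.deletions
        )

    @property
    def deletion_map(self) -> dict[int, int | None]:
        """Reference position -> variant position (1-based) or None if absent."""
        mapping: dict[int, int | None] = {}
        v = 0
        for p in range(1, REFERENCE_LENGTH + 1):
            if p in self.deletions:
                mapping[p] = None
            else:
                v += 1
                mapping[p] = v
        return mapping

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def delete_positions(seq: str, positions: tuple[int, ...]) -> str:
    """Remove the 1-based ``positions`` from a sequence (deletion-variant
    construction helper)."""
    return "".join(c for i, c in enumerate(seq, start=1) if i not in positions)


def default_manifest() -> list[VariantSpec]:
    """The default eight-variant study design: three agonists (the real human
    amylin, rat amylin and pramlintide sequences) plus five synthetic
    full-length antagonist constructs (two low-affinity, three
    high-affinity).

    The antagonist entries are synthetic stand-ins: they carry the class
    structure of amylin-receptor antagonist peptides without claiming their
    real sequences.  They are full-length on purpose: in this design only the
    informative dihedral angles differ between classes, so deletion-driven
    imputation constants cannot leak variant identity into the other angle
    columns.  Deletion variants are fully supported by the feature pipeline
    and can be added to custom manifests via ``deletions``.
    """
    return [
        VariantSpec("human_amylin", HUMAN_AMYLIN, AGONIST),
        VariantSpec("rat_amylin", RAT_AMYLIN, AGONIST),
        VariantSpec("pramlintide", PRAMLINTIDE, AGONIST),
        VariantSpec("low_ant1", HUMAN_AMYLIN, LOW_AFFINITY),
        VariantSpec("low_ant2", HUMAN_AMYLIN, LOW_AFFINITY),
        VariantSpec("high_ant1", HUMAN_AMYLIN, HIGH_AFFINITY),
        VariantSpec("high_ant2", HUMAN_AMYLIN, HIGH_AFFINITY),
        VariantSpec("high_ant3", HUMAN_AMYLIN, HIGH_AFFINITY),
    ]
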