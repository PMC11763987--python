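"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* Multi-model PDB ensembles (one MODEL/ENDMDL block per conformation; backbone
  N, CA, C atoms; optional ACE/NH2 cap pseudo-atoms; chain ``A``; residue ids
  carry reference-amylin numbering so deletions are visible on disk).
  ``REMARK 220`` lines record each model's trajectory and frame index.
* Variant manifests as YAML.
* Imported pairwise structural alignments as TSV (dialect defined below).
* Result tables as CSV.

Alignment-import dialect (tab separated, header ``record pair_id a b``):
``P`` rows give one aligned residue pair (``a`` = position in structure A,
``b`` = position in structure B, both 1-based); ``R`` rows give the pair's
superposition RMSD in Angstrom (``a`` = RMSD, ``b`` empty).  Correspondences
of a pair must be strictly increasing in both coordinates.  Output of other
alignment programs (e.g. flexible aligners) can be converted to this dialect
with a few lines of scripting; see docs/methods.md.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

from .align import PairAlignment
from .synthetic import Conformation, Ensemble
from .variants import VariantSpec

CHAIN_ID = "A"
CAP_C_RES = "ACE"
CAP_N_RES = "NH2"


class PDBFormatError(ValueError):
    """Raised for ensembles that violate the expected PDB layout."""


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment-import files."""


def write_ensemble(ensemble: Ensemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-model PDB file.

    All conformations must belong to the ensemble's variant; an empty
    ensemble is an error, not an empty file.
    """
    confs = ensemble.conformations
    if not confs:
        raise ValueError("refusing to write an empty ensemble")
    names = {c.variant for c in confs}
    if len(names) > 1 or (names and ensemble.name not in names):
        raise ValueError(f"mixed variants in ensemble: {sorted(names)}")
    capped = confs[0].cap_c is not None
    capped_n = confs[0].cap_n is not None
    for c in confs:
        if (c.cap_c is not None) != capped or (c.cap_n is not None) != capped_n:
            raise ValueError("inconsistent capping across conformations")

    n_res = len(ensemble.sequence)
    res_ids, res_names, atom_names, elements, hetero = [], [], [], [], []
    if capped:
        res_ids.append(ensemble.positions[0] - 1)
        res_names.append(CAP_C_RES)
        atom_names.append("C")
        elements.append("C")
        hetero.append(True)
    for pos, letter in zip(ensemble.positions, ensemble.sequence):
        three = ProteinSequence.convert_letter_1to3(letter)
        for an, el in (("N", "N"), ("CA", "C"), ("C", "C")):
            res_ids.append(pos)
            res_names.append(three)
            atom_names.append(an)
            elements.append(el)
            hetero.append(False)
    if capped_n:
        res_ids.append(ensemble.positions[-1] + 1)
        res_names.append(CAP_N_RES)
        atom_names.append("N")
        elements.append("N")
        hetero.append(True)

    n_atoms = len(res_ids)
    stack = struc.AtomArrayStack(len(confs), n_atoms)
    stack.chain_id = np.array([CHAIN_ID] * n_atoms)
    stack.res_id = np.array(res_ids)
    stack.res_name = np.array(res_names)
    stack.atom_name = np.array(atom_names)
    stack.element = np.array(elements)
    stack.hetero = np.array(hetero)
    coords = np.empty((len(confs), n_atoms, 3))
    for i, c in enumerate(confs):
        if c.n_residues != n_res:
            raise ValueError("conformation length differs from sequence")
        coords[i] = np.concatenate(
            ([c.cap_c[None]] if capped else [])
            + [c.coords.reshape(-1, 3)]
            + ([c.cap_n[None]] if capped_n else [])
        )
    stack.coord = coords

    pdbf = PDBFile()
    pdbf.set_structure(stack)
    remarks = [f"REMARK 220 VARIANT {ensemble.name}"]
    for i, c in enumerate(confs):
        remarks.append(f"REMARK 220 MODEL {i + 1} TRAJ {c.trajectory} FRAME {c.frame_index}")
    pdbf.lines = remarks + pdbf.lines
    pdbf.write(str(path))


def _parse_remarks(lines: list[str]) -> tuple[str | None, dict[int, tuple[int, int]]]:
    variant = None
    frame_map: dict[int, tuple[int, int]] = {}
    for line in lines:
        if not line.startswith("REMARK 220"):
            continue
        parts = line.split()
        if len(parts) >= 4 and parts[2] == "VARIANT":
            variant = parts[3]
        elif len(parts) >= 8 and parts[2] == "MODEL":
            frame_map[int(parts[3])] = (int(parts[5]), int(parts[7]))
    return variant, frame_map


def read_ensemble(path: str | os.PathLike) -> Ensemble:
    """Read a multi-model backbone PDB ensemble.

    Every model must contain N, CA and C for every residue of chain A;
    insertion codes and alternate locations are rejected.  The sequence is
    inferred from residue names and the reference positions from residue ids.
    """
    pdbf = PDBFile.read(str(path))
    n_models = pdbf.get_model_count()
    if n_models == 0:
        raise PDBFormatError(f"{path}: no MODEL records")
    variant, frame_map = _parse_remarks(pdbf.lines)
    try:
        stack = pdbf.get_structure(model=None)
    except Exception:
        _diagnose_models(pdbf, path)
        raise
    if np.any(stack.ins_code != ""):
        raise PDBFormatError(f"{path}: insertion codes are not supported")
    if np.any(stack.chain_id != CHAIN_ID):
        raise PDBFormatError(f"{path}: expected a single chain {CHAIN_ID!r}")

    is_cap_c = (stack.res_name == CAP_C_RES)
    is_cap_n = (stack.res_name == CAP_N_RES)
    body = ~(is_cap_c | is_cap_n)
    res_ids = stack.res_id[body]
    atom_names = stack.atom_name[body]
    res_names = stack.res_name[body]

    positions: list[int] = []
    letters: list[str] = []
    i = 0
    while i < len(res_ids):
        rid = res_ids[i]
        block = slice(i, i + 3)
        if (
            i + 3 > len(res_ids)
            or list(atom_names[block]) != ["N", "CA", "C"]
            or len(set(res_ids[block])) != 1
        ):
            missing = _first_incomplete_residue(res_ids, atom_names)
            raise PDBFormatError(
                f"{path}: residue {missing} lacks a complete N/CA/C backbone "
                f"(model 1)"
            )
        positions.append(int(rid))
        letters.append(ProteinSequence.convert_letter_3to1(res_names[i]))
        i += 3
    sequence = "".join(letters)

    body_coords = stack.coord[:, body, :]
    cap_c_coords = stack.coord[:, is_cap_c, :] if is_cap_c.any() else None
    cap_n_coords = stack.coord[:, is_cap_n, :] if is_cap_n.any() else None
    name = variant if variant is not None else Path(path).stem
    confs = []
    for m in range(n_models):
        traj, frame = frame_map.get(m + 1, (0, m))
        confs.append(
            Conformation(
                variant=name,
                frame_index=frame,
                trajectory=traj,
                coords=body_coords[m].reshape(-1, 3, 3),
                cap_c=None if cap_c_coords is None else cap_c_coords[m, 0],
                cap_n=None if cap_n_coords is None else cap_n_coords[m, 0],
            )
        )
    return Ensemble(
        name=name,
        sequence=sequence,
        positions=tuple(positions),
        conformations=confs,
    )


def _first_incomplete_residue(res_ids, atom_names) -> int:
    seen: dict[int, set[str]] = {}
    for rid, an in zip(res_ids, atom_names):
        seen.setdefault(int(rid), set()).add(str(an))
    for rid, atoms in seen.items():
        if atoms != {"N", "CA", "C"}:
            return rid
    return int(res_ids[0]) if len(res_ids) else -1


def _diagnose_models(pdbf: PDBFile, path) -> None:
    """Locate which model breaks the stack layout and raise a named error."""
    ref = None
    for m in range(1, pdbf.get_model_count() + 1):
        arr = pdbf.get_structure(model=m)
        key = list(zip(arr.res_id.tolist(), arr.atom_name.tolist()))
        if ref is None:
            ref = key
        elif key != ref:
            missing = {k for k in ref} - {k for k in key}
            detail = f", missing atom {sorted(missing)[0]}" if missing else ""
        else:
            continue
        if key != ref:
            raise PDBFormatError(
                f"{path}: model {m} is inconsistent with model 1{detail}"
            )


def read_alignment_imports(path: str | os.PathLike) -> list[PairAlignment]:
    """Parse externally computed pairwise alignments (TSV dialect above)."""
    pairs: dict[str, list[tuple[int, int]]] = {}
    rmsds: dict[str, float] = {}
    order: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    if header[:2] != ["record", "pair_id"]:
        raise AlignmentFormatError(
            f"{path}:1: expected header starting with 'record\\tpair_id'"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise AlignmentFormatError(f"{path}:{lineno}: too few fields")
        rec, pair_id = fields[0], fields[1]
        if rec == "P":
            if len(fields) < 4:
                raise AlignmentFormatError(f"{path}:{lineno}: P row needs posA and posB")
            try:
                pos_a, pos_b = int(fields[2]), int(fields[3])
            except ValueError:
                raise AlignmentFormatError(
                    f"{path}:{lineno}: non-integer residue position"
                ) from None
            if pair_id not in pairs:
                pairs[pair_id] = []
                order.append(pair_id)
            prev = pairs[pair_id]
            if any(pa == pos_a for pa, _ in prev):
                raise AlignmentFormatError(
                    f"{path}:{lineno}: duplicate position {pos_a} in pair {pair_id}"
                )
            if prev and not (pos_a > prev[-1][0] and pos_b > prev[-1][1]):
                raise AlignmentFormatError(
                    f"{path}:{lineno}: correspondence not strictly increasing"
                )
            prev.append((pos_a, pos_b))
        elif rec == "R":
            try:
                rmsd = float(fields[2])
            except ValueError:
                raise AlignmentFormatError(f"{path}:{lineno}: bad RMSD value") from None
            if rmsd < 0:
                raise AlignmentFormatError(f"{path}:{lineno}: negative RMSD")
            if pair_id in rmsds:
                raise AlignmentFormatError(
                    f"{path}:{lineno}: duplicate RMSD for pair {pair_id}"
                )
            if pair_id not in pairs:
                pairs[pair_id] = []
                order.append(pair_id)
            rmsds[pair_id] = rmsd
        else:
            raise AlignmentFormatError(
                f"{path}:{lineno}: unknown record type {rec!r}"
            )
    out = []
    for pid in order:
        if pid not in rmsds:
            raise AlignmentFormatError(f"{path}: pair {pid} has no RMSD record")
        out.append(
            PairAlignment(
                pair_id=pid,
                correspondences=tuple(pairs[pid]),
                rmsd=rmsds[pid],
                source="imported",
            )
        )
    return out


def write_alignment_imports(
    alignments: list[PairAlignment], path: str | os.PathLike
) -> None:
    """Write alignments in the TSV import dialect (inverse of the reader)."""
    with open(path, "w") as fh:
        fh.write("record\tpair_id\ta\tb\n")
        for aln in alignments:
            for pa, pb in aln.correspondences:
                fh.write(f"P\t{aln.pair_id}\t{pa}\t{pb}\n")
            fh.write(f"R\t{aln.pair_id}\t{aln.rmsd!r}\t\n")


def write_tables(results: dict[str, pd.DataFrame], directory: str | os.PathLike) -> dict[str, Path]:
    """Write each result table as ``<name>.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in results.items():
        path = directory / f"{name}.csv"
        df.to_csv(path)
        written[name] = path
    return written


def read_manifest(path: str | os.PathLike) -> tuple[list[VariantSpec], dict | None]:
    """Read a YAML variant manifest.

    Returns the variant list plus the optional ``reference`` entry (a dict
    with ``name`` and ``sequence``) describing the alignment partner peptide.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "variants" not in doc:
        raise ValueError(f"{path}: manifest must contain a 'variants' list")
    specs = [
        VariantSpec(
            name=entry["name"],
            sequence=entry["sequence"],
            class_label=entry["class"],
            deletions=tuple(entry.get("deletions", ())),
        )
        for entry in doc["variants"]
    ]
    return specs, doc.get("reference")


def write_manifest(
    specs: list[VariantSpec],
    path: str | os.PathLike,
    reference: dict | None = None,
) -> None:
    doc: dict = {
        "variants": [
            {
                "name": s.name,
                "sequence": s.sequence,
                "class": s.class_label,
                "deletions": list(s.deletions),
            }
            for s in specs
        ]
    }
    if reference is not None:
        doc["reference"] = dict(reference)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
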