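"""Phi/psi feature extraction and the structures x angles feature matrix.

The matrix has exactly 74 columns: ``phi1..phi36``, ``psi1..psi36`` (degrees,
reference-amylin numbering), plus ``class`` and ``variant``.  Angles of
reference residue 37 are excluded by convention: for a 37-residue reference
the 72-column scheme retains positions 1..36.  Rows are indexed by
(variant, trajectory, frame).  Missing values (deleted residues, or chain
termini of uncapped conformations) are NaN until :func:`impute_missing`
replaces them with per-column circular means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import DegenerateGeometryError, dihedrals
from .synthetic import Conformation, Ensemble
from .variants import REFERENCE_LENGTH

#: Largest reference position whose angles enter the matrix.
MAX_ANGLE_POSITION = REFERENCE_LENGTH - 1
#: The 72 angle column names, phi block first.
ANGLE_COLUMNS: tuple[str, ...] = tuple(
    [f"phi{i}" for i in range(1, MAX_ANGLE_POSITION + 1)]
    + [f"psi{i}" for i in range(1, MAX_ANGLE_POSITION + 1)]
)
CLASS_COLUMN = "class"
VARIANT_COLUMN = "variant"
MATRIX_COLUMNS: tuple[str, ...] = ANGLE_COLUMNS + (CLASS_COLUMN, VARIANT_COLUMN)


class ImputationError(ValueError):
    """Raised when a column has no observed values to impute from."""


def extract_phi_psi(
    conformation: Conformation, positions: tuple[int, ...] | None = None
) -> dict[str, float]:
    """Extract backbone dihedrals from one conformation.

    phi(i) is the C(i-1)-N(i)-CA(i)-C(i) torsion, psi(i) the
    N(i)-CA(i)-C(i)-N(i+1) torsion; cap pseudo-atoms stand in for the missing
    neighbours at the termini when present.  Angles undefined at an uncapped
    terminus are returned as NaN.

    Parameters
    ----------
    conformation : Conformation
    positions : tuple of int, optional
        Reference position of each residue (defaults to 1..n); used to name
        the returned angles.

    Returns
    -------
    dict mapping angle name (e.g. ``"psi8"``) to degrees or NaN.
    """
    n = conformation.n_residues
    if positions is None:
        positions = tuple(range(1, n + 1))
    if len(positions) != n:
        raise ValueError("positions length does not match residue count")
    chain = conformation.chain_atoms()
    try:
        tors = dihedrals(chain)
    except DegenerateGeometryError as err:
        raise DegenerateGeometryError(
            f"{err} (variant {conformation.variant}, frame "
            f"{conformation.frame_index})"
        ) from None
    # chain torsion sequence with caps: phi1, psi1, omega1, phi2, psi2, ...
    # without cap_c the first torsion is psi1's predecessor shifted: the first
    # defined torsion is psi1 only if cap_c absent.
    offset = 0 if conformation.cap_c is not None else -1
    out: dict[str, float] = {}
    for k, p in enumerate(positions):
        phi_idx = 3 * k + offset
        psi_idx = 3 * k + 1 + offset
        if phi_idx < 0:
            out[f"phi{p}"] = np.nan
        else:
            out[f"phi{p}"] = float(tors[phi_idx])
        if psi_idx >= len(tors):
            out[f"psi{p}"] = np.nan
        else:
            out[f"psi{p}"] = float(tors[psi_idx])
    return out


def ensemble_angle_table(ensemble: Ensemble) -> pd.DataFrame:
    """Angle table (one row per conformation) extracted from 3D coordinates.

    Columns: ``trajectory``, ``frame`` plus one column per present angle,
    mirroring the layout of :func:`dihedra.synthetic.sample_dihedrals`.
    """
    rows = []
    meta = {"trajectory": [], "frame": []}
    for conf in ensemble.conformations:
        rows.append(extract_phi_psi(conf, ensemble.positions))
        meta["trajectory"].append(conf.trajectory)
        meta["frame"].append(conf.frame_index)
    table = pd.DataFrame(rows)
    table.insert(0, "frame", meta["frame"])
    table.insert(0, "trajectory", meta["trajectory"])
    return table


def assemble_matrix(
    labeled_tables: list[tuple[str, str, pd.DataFrame]],
    frames_per_trajectory: int | None = None,
) -> pd.DataFrame:
    """Assemble the feature matrix from per-variant angle tables.

    Parameters
    ----------
    labeled_tables : list of (variant name, class label, angle table)
        Angle tables as produced by ``sample_dihedrals`` or
        ``ensemble_angle_table`` (columns ``trajectory``, ``frame``, angles
        named by reference position).
    frames_per_trajectory : int, optional
        If given, keep only the last that many frames of each trajectory.

    Returns
    -------
    DataFrame with the 74 fixed columns and a (variant, trajectory, frame)
    row index.  Angle columns whose reference position is absent from a
    variant are NaN for that variant's rows.
    """
    blocks = []
    for name, class_label, table in labeled_tables:
        tab = table
        if frames_per_trajectory is not None:
            tab = (
                tab.sort_values(["trajectory", "frame"])
                .groupby("trajectory", group_keys=False)
                .tail(frames_per_trajectory)
            )
        block = pd.DataFrame(
            np.nan, index=range(len(tab)), columns=list(ANGLE_COLUMNS)
        )
        for col in tab.columns:
            if col in ("trajectory", "frame"):
                continue
            if col in block.columns:
                block[col] = tab[col].to_numpy()
            # angles beyond MAX_ANGLE_POSITION (e.g. residue 37) are dropped
        block[CLASS_COLUMN] = class_label
        block[VARIANT_COLUMN] = name
        block.index = pd.MultiIndex.from_arrays(
            [
                [name] * len(tab),
                tab["trajectory"].to_numpy(),
                tab["frame"].to_numpy(),
            ],
            names=["variant", "trajectory", "frame"],
        )
        blocks.append(block)
    if not blocks:
        raise ValueError("no angle tables given")
    return pd.concat(blocks)


def matrix_from_ensembles(
    ensembles: list[Ensemble], frames_per_trajectory: int | None = None
) -> pd.DataFrame:
    """Extract dihedrals from 3D ensembles and assemble the feature matrix."""
    for ens in ensembles:
        if ens.class_label is None:
            raise ValueError(f"ensemble {ens.name!r} has no class label")
    return assemble_matrix(
        [(e.name, e.class_label, ensemble_angle_table(e)) for e in ensembles],
        frames_per_trajectory=frames_per_trajectory,
    )


def circular_mean_deg(values: np.ndarray) -> float:
    """Resultant-vector (circular) mean of angles in degrees, in (-180, 180]."""
    rad = np.radians(np.asarray(values, dtype=float))
    mean = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    if mean <= -180.0:
        mean += 360.0
    return float(mean)


def impute_missing(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing angle cell by the circular mean of the observed
    values in its column.  Observed cells are untouched; the operation is
    idempotent.

    Raises
    ------
    ImputationError
        If an angle column has no observed values at all.
    """
    out = matrix.copy()
    for col in ANGLE_COLUMNS:
        vals = out[col]
        missing = vals.isna()
        if not missing.any():
            continue
        observed = vals[~missing]
        if observed.empty:
            raise ImputationError(f"column {col!r} is fully missing")
        out.loc[missing, col] = circular_mean_deg(observed.to_numpy())
    return out
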