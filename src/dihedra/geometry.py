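"""Low-level backbone geometry: torsion angles, internal-coordinate chain
building (NeRF) and optimal rigid superposition (Kabsch).

All angles at this layer are in degrees; coordinates in Angstrom.
"""

from __future__ import annotations

import numpy as np

# Idealised backbone geometry for a trans polypeptide chain.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0

_DEGENERATE_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is undefined because three atoms are colinear."""


def wrap_degrees(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into the interval (-180, 180]."""
    wrapped = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle):
        return float(wrapped)
    return wrapped


def dihedrals(points: np.ndarray) -> np.ndarray:
    """Torsion angles for every consecutive atom quadruple along a chain.

    Parameters
    ----------
    points : (m, 3) array
        Atom positions in chain order.

    Returns
    -------
    (m - 3,) array of torsions in degrees, IUPAC sign convention
    (clockwise rotation of the far bond viewed along the central bond is
    positive).

    Raises
    ------
    DegenerateGeometryError
        If any three consecutive atoms are colinear, naming the offending
        quadruple index.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 4:
        raise ValueError("need an (m, 3) array with m >= 4")
    b1 = p[1:-2] - p[:-3]
    b2 = p[2:-1] - p[1:-2]
    b3 = p[3:] - p[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1_norm = np.linalg.norm(n1, axis=1)
    n2_norm = np.linalg.norm(n2, axis=1)
    bad = (n1_norm < _DEGENERATE_TOL) | (n2_norm < _DEGENERATE_TOL)
    if np.any(bad):
        idx = int(np.nonzero(bad)[0][0])
        raise DegenerateGeometryError(
            f"colinear atom triple in quadruple starting at chain atom {idx}"
        )
    b2u = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m1 = np.cross(n1, b2u)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    # IUPAC sign convention (matches biotite/biopython/MDAnalysis)
    return -np.degrees(np.arctan2(y, x))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle (degrees) of a single atom quadruple."""
    return float(dihedrals(np.stack([p0, p1, p2, p3]).astype(float))[0])


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given atoms A, B, C, the C-D bond length, the B-C-D bond
    angle and the A-B-C-D torsion (NeRF construction)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < _DEGENERATE_TOL:
        raise DegenerateGeometryError("colinear reference atoms in NeRF placement")
    n /= n_norm
    m = np.cross(n, bc)
    frame = np.stack([bc, m, n], axis=1)
    return c + frame @ d_local


def build_chain(torsions: np.ndarray, bonds: np.ndarray, angles: np.ndarray,
                seed_atoms: np.ndarray) -> np.ndarray:
    """Extend a 3-atom seed into a full chain from internal coordinates.

    ``bonds[k]``/``angles[k]``/``torsions[k]`` describe the placement of chain
    atom ``k + 3`` relative to its three predecessors.
    """
    n_total = len(torsions) + 3
    out = np.empty((n_total, 3))
    out[:3] = seed_atoms
    for k in range(len(torsions)):
        out[k + 3] = place_atom(out[k], out[k + 1], out[k + 2],
                                bonds[k], angles[k], torsions[k])
    return out


def _kabsch_sum_singular(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Chirality-corrected sum of singular values of the cross-covariance for
    batches of centered point sets ``p``, ``q`` of shape (..., m, 3)."""
    h = np.einsum("...mi,...mj->...ij", p, q)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(u) * np.linalg.det(vt)
    s_sum = s[..., 0] + s[..., 1] + np.sign(det) * s[..., 2]
    return s_sum


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two equal-size point sets over all rigid
    superpositions (rotations + translations, reflections excluded).

    Computed from the explicit superposition residuals, which avoids the
    cancellation error of the singular-value shortcut near zero RMSD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    r, t = kabsch_rotation(b, a)
    residuals = b @ r.T + t - a
    return float(np.sqrt((residuals**2).sum() / len(a)))


def kabsch_rmsd_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched Kabsch RMSD for paired point sets of shape (..., m, 3)."""
    m = a.shape[-2]
    pa = a - a.mean(axis=-2, keepdims=True)
    pb = b - b.mean(axis=-2, keepdims=True)
    e0 = np.einsum("...mi,...mi->...", pa, pa) + np.einsum("...mi,...mi->...", pb, pb)
    s_sum = _kabsch_sum_singular(pa, pb)
    msd = np.maximum(e0 - 2.0 * s_sum, 0.0) / m
    return np.sqrt(msd)


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation matrix R and translation t superposing ``mobile`` onto
    ``target`` (both (m, 3)): ``mobile @ R.T + t ~ target``."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = ct - r @ cm
    return r, t


def pairwise_ca_rmsd(coords: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Full symmetric RMSD matrix for a stack of conformations.

    Parameters
    ----------
    coords : (n, m, 3) array
        n conformations of m points each.
    chunk : int
        Row-block size; limits the memory of the batched SVD.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    centered = coords - coords.mean(axis=1, keepdims=True)
    norms = np.einsum("nmi,nmi->n", centered, centered)
    out = np.zeros((n, n))
    m = coords.shape[1]
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        block = centered[i0:i1]  # (bi, m, 3)
        h = np.einsum("bmi,nmj->bnij", block, centered)
        u, s, vt = np.linalg.svd(h)
        det = np.linalg.det(u) * np.linalg.det(vt)
        s_sum = s[..., 0] + s[..., 1] + np.sign(det) * s[..., 2]
        e0 = norms[i0:i1, None] + norms[None, :]
        msd = np.maximum(e0 - 2.0 * s_sum, 0.0) / m
        out[i0:i1] = np.sqrt(msd)
    np.fill_diagonal(out, 0.0)
    return out
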