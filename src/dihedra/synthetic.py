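"""Synthetic conformational-ensemble generator.

Emulates the statistical structure of enhanced-sampling MD output: for each
peptide variant, ``n_trajectories`` x ``frames_per_trajectory`` backbone
conformations whose phi/psi distributions are von Mises, with a small set of
"informative" angles whose mean direction differs between functional classes.
Backbones are reconstructed from the sampled torsions by sequential
internal-coordinate (NeRF) placement with idealised bond lengths/angles and a
trans peptide bond (omega = 180 deg), so extracted dihedrals reproduce the
sampled ones exactly.  Chains are capped by default with an acetyl-like
carbonyl carbon and an amide-like nitrogen so that phi of the first and psi of
the last residue are defined, mirroring capped-termini simulation setups.

The generator targets statistical realism only: no side chains, no steric
checks, no energetics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    ANGLE_C_N_CA,
    ANGLE_CA_C_N,
    ANGLE_N_CA_C,
    BOND_C_N,
    BOND_CA_C,
    BOND_N_CA,
    OMEGA_TRANS,
    place_atom,
    wrap_degrees,
)
from .variants import AGONIST, CLASS_ORDER, HIGH_AFFINITY, LOW_AFFINITY, VariantSpec

#: Angles whose class-dependent mean directions carry the functional signal in
#: the default design.  psi8 and psi19 each separate the agonist class from
#: the rest; psi20 and phi9 each separate the low-affinity antagonists from
#: the rest; high-affinity antagonists are the residual class.  Any selection
#: round therefore needs one angle of each kind, and two rounds jointly
#: recover all four.
DEFAULT_INFORMATIVE_ANGLES = frozenset({"psi8", "psi20", "phi9", "psi19"})

#: Mean dihedral direction (degrees) per class for the informative angles.
#: Class separations are >= 60 deg everywhere (150-180 deg in practice).
DEFAULT_ANGLE_MEANS: dict[str, dict[str, float]] = {
    AGONIST: {"psi8": -130.0, "psi19": 100.0, "psi20": -70.0, "phi9": -60.0},
    LOW_AFFINITY: {"psi8": 30.0, "psi19": -80.0, "psi20": 100.0, "phi9": 120.0},
    HIGH_AFFINITY: {"psi8": 30.0, "psi19": -80.0, "psi20": -70.0, "phi9": -60.0},
}


class GenerationError(ValueError):
    """Raised when a backbone cannot be generated from the given angles."""


class ConfigurationError(ValueError):
    """Raised for invalid ensemble parameters."""


@dataclass(frozen=True)
class EnsembleParams:
    """Parameters of the synthetic ensemble design.

    Attributes
    ----------
    n_trajectories, frames_per_trajectory : int
        Ensemble layout; default 3 x 1000 retained frames.
    angle_means : mapping class -> {angle name -> mean direction, degrees}
        Class-specific mean overrides.  Angles not listed fall back to
        ``base_phi_mean`` / ``base_psi_mean`` (shared across classes).
    angle_concentrations : mapping angle name -> von Mises kappa
        Per-angle overrides of ``default_concentration``.
    informative_angles : frozenset of angle names
        The angles whose means are declared to differ across classes.
    seed : int
        Base seed; each variant derives an independent stream from it.
    """

    n_trajectories: int = 3
    frames_per_trajectory: int = 1000
    angle_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ANGLE_MEANS.items()}
    )
    angle_concentrations: dict[str, float] = field(default_factory=dict)
    default_concentration: float = 8.0
    base_phi_mean: float = -100.0
    base_psi_mean: float = 120.0
    informative_angles: frozenset = DEFAULT_INFORMATIVE_ANGLES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 1 or self.frames_per_trajectory < 1:
            raise ConfigurationError("ensemble layout counts must be >= 1")
        if self.default_concentration <= 0 or any(
            k <= 0 for k in self.angle_concentrations.values()
        ):
            raise ConfigurationError("von Mises concentrations must be > 0")
        declared: set[str] = set()
        for cls, means in self.angle_means.items():
            if cls not in CLASS_ORDER:
                raise ConfigurationError(f"unknown class label {cls!r} in angle_means")
            declared |= set(means)
            for name, mu in means.items():
                if not (-180.0 < mu <= 180.0):
                    raise ConfigurationError(
                        f"mean for {name!r} ({cls}) outside (-180, 180]"
                    )
        if not self.informative_angles <= declared and self.informative_angles:
            missing = set(self.informative_angles) - declared
            if missing:
                raise ConfigurationError(
                    f"informative angles {sorted(missing)} have no declared means"
                )

    def mean_for(self, class_label: str, angle: str) -> float:
        over = self.angle_means.get(class_label, {})
        if angle in over:
            return over[angle]
        return self.base_phi_mean if angle.startswith("phi") else self.base_psi_mean

    def kappa_for(self, angle: str) -> float:
        return self.angle_concentrations.get(angle, self.default_concentration)


@dataclass
class Conformation:
    """One backbone conformation: N, CA, C coordinates per residue (Angstrom),
    plus optional terminal cap pseudo-atoms (acetyl carbonyl C, amide N)."""

    variant: str
    frame_index: int
    coords: np.ndarray  # (n_residues, 3, 3): atoms N, CA, C
    trajectory: int = 0
    cap_c: np.ndarray | None = None
    cap_n: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (3, 3):
            raise ValueError("coords must have shape (n_residues, 3, 3)")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def ca(self) -> np.ndarray:
        """(n_residues, 3) C-alpha coordinates."""
        return self.coords[:, 1, :]

    def chain_atoms(self) -> np.ndarray:
        """All chain atoms in order, caps included when present."""
        parts = []
        if self.cap_c is not None:
            parts.append(self.cap_c[None, :])
        parts.append(self.coords.reshape(-1, 3))
        if self.cap_n is not None:
            parts.append(self.cap_n[None, :])
        return np.concatenate(parts, axis=0)


@dataclass
class Ensemble:
    """A set of conformations of one variant."""

    name: str
    sequence: str
    positions: tuple[int, ...]  # reference positions of each residue
    conformations: list[Conformation]
    class_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.sequence):
            raise ValueError("positions and sequence lengths differ")

    def __len__(self) -> int:
        return len(self.conformations)

    def ca_stack(self) -> np.ndarray:
        """(n_conformations, n_residues, 3) C-alpha coordinate stack."""
        return np.stack([c.ca for c in self.conformations])


def angle_names_for(positions: tuple[int, ...]) -> list[str]:
    """Column order of a variant's angle table: phi then psi, by position."""
    return [f"phi{p}" for p in positions] + [f"psi{p}" for p in positions]


def variant_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-variant random stream derived from the base seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def sample_dihedrals(spec: VariantSpec, params: EnsembleParams) -> pd.DataFrame:
    """Draw per-frame phi/psi angles for one variant.

    Returns a DataFrame with columns ``trajectory``, ``frame`` and one column
    per angle of the variant's present residues, values in degrees in
    (-180, 180].  Deterministic given ``params.seed`` and the variant name.
    """
    rng = variant_rng(params.seed, spec.name)
    n = params.n_trajectories * params.frames_per_trajectory
    names = angle_names_for(spec.present_positions)
    data = {
        "trajectory": np.repeat(
            np.arange(params.n_trajectories), params.frames_per_trajectory
        ),
        "frame": np.tile(
            np.arange(params.frames_per_trajectory), params.n_trajectories
        ),
    }
    for name in names:
        mu = params.mean_for(spec.class_label, name)
        kappa = params.kappa_for(name)
        draws = rng.vonmises(np.radians(mu), kappa, size=n)
        data[name] = wrap_degrees(np.degrees(draws))
    return pd.DataFrame(data)


def _seed_atoms(capped: bool) -> np.ndarray:
    """Canonical placement of the first three chain atoms in the xy plane."""
    if capped:
        # cap C, N1, CA1
        first = np.zeros(3)
        second = np.array([BOND_C_N, 0.0, 0.0])
        theta = np.radians(180.0 - ANGLE_C_N_CA)
        third = second + BOND_N_CA * np.array([np.cos(theta), np.sin(theta), 0.0])
    else:
        # N1, CA1, C1
        first = np.zeros(3)
        second = np.array([BOND_N_CA, 0.0, 0.0])
        theta = np.radians(180.0 - ANGLE_N_CA_C)
        third = second + BOND_CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])
    return np.stack([first, second, third])


def _internal_coords(
    angles: pd.DataFrame | dict, positions: tuple[int, ...], capped: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bond/angle/torsion arrays for every chain atom beyond the 3-atom seed.

    Torsions may be a single mapping (one frame) or a DataFrame (many frames);
    the returned torsion array has shape (n_frames, n_placements).
    """
    if isinstance(angles, pd.DataFrame):
        table = angles
    else:
        table = pd.DataFrame([angles])

    def col(name: str) -> np.ndarray:
        if name not in table:
            raise GenerationError(f"missing angle {name!r} for a present residue")
        vals = table[name].to_numpy(dtype=float)
        if np.any(np.isnan(vals)):
            raise GenerationError(f"missing angle {name!r} for a present residue")
        return vals

    n_frames = len(table)
    bonds: list[float] = []
    bangles: list[float] = []
    torsions: list[np.ndarray] = []
    omega = np.full(n_frames, OMEGA_TRANS)
    for k, p in enumerate(positions):
        if k == 0:
            if capped:
                # seed is capC-N1-CA1; place C1 with torsion phi1
                bonds.append(BOND_CA_C)
                bangles.append(ANGLE_N_CA_C)
                torsions.append(col(f"phi{p}"))
            # uncapped: seed already contains C1; phi1 is unused
            continue
        prev = positions[k - 1]
        # N_k from psi of previous residue
        bonds.append(BOND_C_N)
        bangles.append(ANGLE_CA_C_N)
        torsions.append(col(f"psi{prev}"))
        # CA_k via the trans peptide bond
        bonds.append(BOND_N_CA)
        bangles.append(ANGLE_C_N_CA)
        torsions.append(omega)
        # C_k from phi of this residue
        bonds.append(BOND_CA_C)
        bangles.append(ANGLE_N_CA_C)
        torsions.append(col(f"phi{p}"))
    if capped:
        last = positions[-1]
        bonds.append(BOND_C_N)
        bangles.append(ANGLE_CA_C_N)
        torsions.append(col(f"psi{last}"))
    return (
        np.asarray(bonds),
        np.asarray(bangles),
        np.stack(torsions, axis=1) if torsions else np.empty((n_frames, 0)),
    )


def _place_atoms_batch(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: np.ndarray,
) -> np.ndarray:
    """Vectorised NeRF placement over a batch of frames ((n, 3) inputs)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)[:, None]
    d_local = bond * np.concatenate(
        [
            np.broadcast_to(-np.cos(theta), chi.shape),
            np.sin(theta) * np.cos(chi),
            np.sin(theta) * np.sin(chi),
        ],
        axis=1,
    )
    bc = c - b
    bc /= np.linalg.norm(bc, axis=1, keepdims=True)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    frame = np.stack([bc, m, n], axis=2)
    return c + np.einsum("nij,nj->ni", frame, d_local)


def build_backbones(
    angles: pd.DataFrame, positions: tuple[int, ...], capped: bool = True
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Build backbones for a whole angle table at once.

    Returns ``(coords, cap_c, cap_n)`` with coords of shape
    (n_frames, n_residues, 3, 3); cap arrays are None when uncapped.
    """
    if not positions:
        raise GenerationError("empty residue list")
    bonds, bangles, torsions = _internal_coords(angles, positions, capped)
    n_frames = torsions.shape[0]
    n_atoms = 3 + len(bonds)
    chain = np.empty((n_frames, n_atoms, 3))
    chain[:, :3] = _seed_atoms(capped)[None]
    for k in range(len(bonds)):
        chain[:, k + 3] = _place_atoms_batch(
            chain[:, k], chain[:, k + 1], chain[:, k + 2],
            bonds[k], bangles[k], torsions[:, k],
        )
    if capped:
        cap_c = chain[:, 0]
        cap_n = chain[:, -1]
        backbone = chain[:, 1:-1]
    else:
        cap_c = cap_n = None
        backbone = chain
    coords = backbone.reshape(n_frames, len(positions), 3, 3)
    return coords, cap_c, cap_n


def build_backbone(
    angles: dict | pd.Series,
    spec: VariantSpec,
    capped: bool = True,
    frame_index: int = 0,
    trajectory: int = 0,
) -> Conformation:
    """Build a single conformation from one row of phi/psi angles."""
    if isinstance(angles, pd.Series):
        angles = angles.to_dict()
    coords, cap_c, cap_n = build_backbones(
        pd.DataFrame([angles]), spec.present_positions, capped=capped
    )
    return Conformation(
        variant=spec.name,
        frame_index=frame_index,
        trajectory=trajectory,
        coords=coords[0],
        cap_c=None if cap_c is None else cap_c[0],
        cap_n=None if cap_n is None else cap_n[0],
    )


def generate_ensemble(
    spec: VariantSpec, params: EnsembleParams, capped: bool = True
) -> Ensemble:
    """Sample dihedrals for a variant and build the full 3D ensemble."""
    angles = sample_dihedrals(spec, params)
    coords, cap_c, cap_n = build_backbones(
        angles, spec.present_positions, capped=capped
    )
    confs = [
        Conformation(
            variant=spec.name,
            frame_index=int(angles["frame"].iat[i]),
            trajectory=int(angles["trajectory"].iat[i]),
            coords=coords[i],
            cap_c=None if cap_c is None else cap_c[i],
            cap_n=None if cap_n is None else cap_n[i],
        )
        for i in range(len(angles))
    ]
    return Ensemble(
        name=spec.name,
        sequence=spec.sequence,
        positions=spec.present_positions,
        conformations=confs,
        class_label=spec.class_label,
    )


def generate_reference_ensemble(
    name: str, sequence: str, params: EnsembleParams, capped: bool = True
) -> Ensemble:
    """Generate a class-free reference ensemble (e.g. the alignment partner
    peptide): every angle is drawn from the shared base distribution."""
    positions = tuple(range(1, len(sequence) + 1))
    rng = variant_rng(params.seed, name)
    n = params.n_trajectories * params.frames_per_trajectory
    data = {
        "trajectory": np.repeat(
            np.arange(params.n_trajectories), params.frames_per_trajectory
        ),
        "frame": np.tile(
            np.arange(params.frames_per_trajectory), params.n_trajectories
        ),
    }
    for aname in angle_names_for(positions):
        mu = params.base_phi_mean if aname.startswith("phi") else params.base_psi_mean
        draws = rng.vonmises(np.radians(mu), params.kappa_for(aname), size=n)
        data[aname] = wrap_degrees(np.degrees(draws))
    angles = pd.DataFrame(data)
    coords, cap_c, cap_n = build_backbones(angles, positions, capped=capped)
    confs = [
        Conformation(
            variant=name,
            frame_index=int(angles["frame"].iat[i]),
            trajectory=int(angles["trajectory"].iat[i]),
            coords=coords[i],
            cap_c=None if cap_c is None else cap_c[i],
            cap_n=None if cap_n is None else cap_n[i],
        )
        for i in range(len(angles))
    ]
    return Ensemble(
        name=name,
        sequence=sequence,
        positions=positions,
        conformations=confs,
        class_label=None,
    )
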