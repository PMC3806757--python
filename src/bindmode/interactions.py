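"""Geometric interaction fingerprints: hydrogen bonds, ion coordination,
dihedrals, rotamer classes and 2-D kernel density maps.

Hydrogen bonds use distance + angle criteria (donor-heavy–acceptor distance
≤ 3.5 Å and, when explicit hydrogens are present, D–H···A angle ≥ 135°);
structures without hydrogens fall back to the distance criterion alone.
Angles are degrees throughout, wrapped to (−180°, 180°].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structures import Structure, Trajectory

DIST_CUTOFF = 3.5    # Å, donor-heavy to acceptor
ANGLE_CUTOFF = 135.0  # degrees, D–H···A
COORDINATION_CUTOFF = 2.6  # Å, ion to O/N, closed interval
DH_BOND_MAX = 1.25   # Å, covalent D–H search radius


class GeometryError(ValueError):
    """Raised for degenerate geometry (e.g. collinear dihedral points)."""


@dataclass(frozen=True)
class HBond:
    donor_atom_id: int
    acceptor_atom_id: int
    frame: int
    distance: float
    angle: float | None = None


@dataclass(frozen=True)
class CoordinationSphere:
    ion_atom_id: int
    frame: int
    coordinating_atom_ids: tuple
    coordination_number: int

    def __post_init__(self):
        if self.coordination_number != len(self.coordinating_atom_ids):
            raise ValueError("coordination_number must equal the list length")


@dataclass
class DihedralSeries:
    name: str
    atom_quadruple: tuple
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.size and (
            self.values.min() <= -180.0 - 1e-9 or self.values.max() > 180.0 + 1e-9
        ):
            raise ValueError("dihedral values must be wrapped to (−180°, 180°]")


# --------------------------------------------------------------------------
# Hydrogen bonds
# --------------------------------------------------------------------------

def _attached_hydrogens(structure: Structure, donor_idx: int, pos: np.ndarray) -> np.ndarray:
    d = structure.atoms[donor_idx]
    idx = [
        i
        for i, a in enumerate(structure.atoms)
        if a.element == "H"
        and a.residue_index == d.residue_index
        and np.linalg.norm(pos[i] - pos[donor_idx]) <= DH_BOND_MAX
    ]
    return np.array(idx, int)


def detect_hbonds(
    structure: Structure,
    coords=None,
    dist_cutoff: float = DIST_CUTOFF,
    angle_cutoff: float = ANGLE_CUTOFF,
    frame: int = 0,
) -> list[HBond]:
    """Hydrogen bonds in one snapshot.

    Donor/acceptor roles come from the per-atom annotations. The angle
    criterion applies per donor only when that donor has an attached explicit
    hydrogen; hydrogen-free structures are scored on distance alone.
    """
    pos = structure.positions if coords is None else np.asarray(coords, float)
    donors = [i for i, a in enumerate(structure.atoms) if "donor_heavy" in a.hbond_roles]
    acceptors = [i for i, a in enumerate(structure.atoms) if "acceptor" in a.hbond_roles]
    if not donors or not acceptors:
        warnings.warn("no annotated donors/acceptors; empty hydrogen-bond list")
        return []
    d = cdist(pos[donors], pos[acceptors])
    out = []
    for di, donor_idx in enumerate(donors):
        hyd = _attached_hydrogens(structure, donor_idx, pos)
        for ai, acc_idx in enumerate(acceptors):
            if structure.atoms[donor_idx].residue_index == structure.atoms[acc_idx].residue_index:
                continue
            if d[di, ai] > dist_cutoff:
                continue
            angle = None
            if len(hyd):
                angle = max(
                    _angle_deg(pos[h], pos[donor_idx], pos[acc_idx], vertex_first=True)
                    for h in hyd
                )
                if angle < angle_cutoff:
                    continue
            out.append(
                HBond(
                    donor_atom_id=structure.atoms[donor_idx].atom_id,
                    acceptor_atom_id=structure.atoms[acc_idx].atom_id,
                    frame=frame,
                    distance=float(d[di, ai]),
                    angle=angle,
                )
            )
    return out


def _angle_deg(p_h, p_d, p_a, vertex_first: bool = True) -> float:
    """D–H···A angle at the hydrogen (degrees)."""
    v1 = np.asarray(p_d, float) - np.asarray(p_h, float)
    v2 = np.asarray(p_a, float) - np.asarray(p_h, float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def hbond_occupancy(
    trajectory: Trajectory,
    donor_atom_id: int,
    acceptor_atom_id: int,
    dist_cutoff: float = DIST_CUTOFF,
    angle_cutoff: float = ANGLE_CUTOFF,
) -> float:
    """Fraction of frames in which one donor–acceptor pair is hydrogen bonded."""
    s = trajectory.structure
    di = s.index_of(donor_atom_id)
    ai = s.index_of(acceptor_atom_id)
    if trajectory.n_frames < 1:
        raise ValueError("trajectory has no frames")
    hits = 0
    for f in range(trajectory.n_frames):
        pos = trajectory.coords[f]
        if np.linalg.norm(pos[di] - pos[ai]) > dist_cutoff:
            continue
        hyd = _attached_hydrogens(s, di, pos)
        if len(hyd):
            angle = max(_angle_deg(pos[h], pos[di], pos[ai]) for h in hyd)
            if angle < angle_cutoff:
                continue
        hits += 1
    return hits / trajectory.n_frames


# --------------------------------------------------------------------------
# Ion coordination
# --------------------------------------------------------------------------

def coordination_sphere(
    structure: Structure,
    ion_atom_id: int,
    cutoff: float = COORDINATION_CUTOFF,
    coords=None,
    frame: int = 0,
) -> CoordinationSphere:
    """O/N atoms within ``cutoff`` (closed interval) of one ion."""
    idx = structure.index_of(ion_atom_id)
    if structure.atoms[idx].entity != "ion":
        raise ValueError(f"atom {ion_atom_id} is not an ion")
    pos = structure.positions if coords is None else np.asarray(coords, float)
    dist = np.linalg.norm(pos - pos[idx], axis=1)
    elems = np.array([a.element for a in structure.atoms])
    hits = np.nonzero((dist <= cutoff) & np.isin(elems, ["O", "N"]) & (np.arange(len(dist)) != idx))[0]
    ids = tuple(int(structure.atoms[i].atom_id) for i in hits)
    return CoordinationSphere(ion_atom_id, frame, ids, len(ids))


def coordination_numbers(
    trajectory: Trajectory, ion_atom_id: int, cutoff: float = COORDINATION_CUTOFF
) -> np.ndarray:
    """Per-frame coordination number of one ion."""
    return np.array(
        [
            coordination_sphere(
                trajectory.structure, ion_atom_id, cutoff, trajectory.coords[f], f
            ).coordination_number
            for f in range(trajectory.n_frames)
        ]
    )


# --------------------------------------------------------------------------
# Dihedrals and rotamers
# --------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, (−180°, 180°].

    Sign convention: looking along the p2→p3 axis, a clockwise rotation of
    the far bond relative to the near bond is positive (cis = 0°).
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("three collinear points: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2n)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def compute_dihedral_series(
    trajectory: Trajectory, atom_ids: tuple, name: str = "dihedral"
) -> DihedralSeries:
    """Per-frame dihedral defined by four atom ids."""
    idx = [trajectory.structure.index_of(a) for a in atom_ids]
    values = np.array(
        [dihedral(*(trajectory.coords[f][i] for i in idx)) for f in range(trajectory.n_frames)]
    )
    return DihedralSeries(name=name, atom_quadruple=tuple(atom_ids), values=values)


def classify_rotamer(angle_deg: float) -> str:
    """gauche+ on (0°, 120°], gauche− on (−120°, 0°], trans otherwise."""
    if not (-180.0 < angle_deg <= 180.0 + 1e-12):
        raise ValueError("angle must be wrapped to (−180°, 180°]")
    if 0.0 < angle_deg <= 120.0:
        return "gauche+"
    if -120.0 < angle_deg <= 0.0:
        return "gauche-"
    return "trans"


def rotamer_fractions(values) -> dict[str, float]:
    """Fraction of samples in each rotamer bin."""
    values = np.asarray(values, float)
    labels = [classify_rotamer(v) for v in values]
    return {
        k: labels.count(k) / len(labels) for k in ("gauche-", "trans", "gauche+")
    }


# --------------------------------------------------------------------------
# 2-D kernel density
# --------------------------------------------------------------------------

def silverman_bandwidth(x: np.ndarray) -> float:
    """Per-axis Silverman rule for a 2-D product kernel: σ·n^(−1/6)."""
    x = np.asarray(x, float)
    return float(np.std(x, ddof=1) * len(x) ** (-1.0 / 6.0))


def kde2d(
    samples: np.ndarray,
    bandwidths: tuple | None = None,
    grid_size: int = 100,
    padding: float = 3.0,
):
    """Axis-aligned bivariate normal KDE on a square grid.

    Returns (x_grid, y_grid, density) where density[i, j] is evaluated at
    (x_grid[i], y_grid[j]); the grid extends ``padding`` bandwidths beyond the
    data on each axis and has equal resolution per axis. The density
    integrates to 1 over the plane.
    """
    samples = np.asarray(samples, float)
    if samples.ndim != 2 or samples.shape[1] != 2 or len(samples) < 2:
        raise ValueError("need at least 2 two-dimensional samples")
    if bandwidths is None:
        bandwidths = (silverman_bandwidth(samples[:, 0]), silverman_bandwidth(samples[:, 1]))
    hx, hy = (float(b) for b in bandwidths)
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")
    n = len(samples)
    xg = np.linspace(samples[:, 0].min() - padding * hx, samples[:, 0].max() + padding * hx, grid_size)
    yg = np.linspace(samples[:, 1].min() - padding * hy, samples[:, 1].max() + padding * hy, grid_size)
    kx = np.exp(-0.5 * ((xg[:, None] - samples[None, :, 0]) / hx) ** 2)
    ky = np.exp(-0.5 * ((yg[:, None] - samples[None, :, 1]) / hy) ** 2)
    dens = kx @ ky.T / (n * 2.0 * np.pi * hx * hy)
    return xg, yg, dens
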