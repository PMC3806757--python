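"""Single-point end-point energy engine (MM-GBSA style) for toy complexes.

Per-snapshot binding energy in the single-trajectory approximation: the
complex, receptor and ligand share coordinates, so the molecular-mechanics
terms reduce to cross-partition pair sums while the solvation terms are
computed as complex − receptor − ligand.

Components (kcal/mol):

* ``vdw`` — 12-6 Lennard-Jones with Lorentz–Berthelot combining,
* ``ele`` — Coulomb with internal dielectric 1, k_e = 332.0636 kcal·Å/(mol·e²),
* ``gb_polar`` — canonical pairwise generalized-Born polar solvation with the
  Still f_GB smoothing and fixed per-element Born radii (a deterministic
  simplification of effective-radii schemes),
* ``nonpolar`` — γ·SASA + β with a sphere-point (Shrake–Rupley) numerical
  solvent-accessible surface area.

Also houses the water-mobility analysis (crystallographic-style B-factors)
used to pick conserved "key" waters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structures import BindingPartition, Structure, Trajectory

KCAL_COULOMB = 332.0636  # kcal·Å/(mol·e²)


class EnergyError(ValueError):
    """Raised for invalid energy-evaluation inputs (e.g. coincident atoms)."""


@dataclass(frozen=True)
class EnergyParams:
    """Engine parameters: dielectrics, nonpolar surface coefficients, SASA grid."""

    eps_in: float = 1.0
    eps_out: float = 80.0
    gamma: float = 0.0072      # kcal/(mol·Å²)
    beta: float = 0.0          # kcal/mol
    probe_radius: float = 1.4  # Å
    sasa_points: int = 256

    def __post_init__(self):
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise EnergyError("dielectric constants must be positive")
        if self.probe_radius < 0:
            raise EnergyError("probe radius must be non-negative")


@dataclass(frozen=True)
class EnergyComponents:
    vdw: float
    ele: float
    gb_polar: float
    nonpolar: float
    total: float

    def __post_init__(self):
        if abs(self.total - (self.vdw + self.ele + self.gb_polar + self.nonpolar)) > 1e-9:
            raise EnergyError("total must equal the sum of the four components")

    @classmethod
    def from_parts(cls, vdw, ele, gb_polar, nonpolar) -> "EnergyComponents":
        return cls(vdw, ele, gb_polar, nonpolar, vdw + ele + gb_polar + nonpolar)


def _coords(structure: Structure, coords) -> np.ndarray:
    if coords is None:
        return structure.positions
    coords = np.asarray(coords, float)
    if coords.shape != (len(structure), 3):
        raise EnergyError(f"coords shape {coords.shape} does not match structure")
    return coords


def _cross_distances(pos, rec_mask, lig_mask) -> np.ndarray:
    r = cdist(pos[rec_mask], pos[lig_mask])
    if r.size and r.min() <= 1e-12:
        raise EnergyError("coincident atoms across the binding partition (r = 0)")
    return r


def coulomb_energy(
    structure: Structure, partition: BindingPartition, coords=None
) -> float:
    """Cross-partition Coulomb energy, internal dielectric 1, no cutoff."""
    pos = _coords(structure, coords)
    rec, lig = partition.masks(structure)
    r = _cross_distances(pos, rec, lig)
    q = structure.charges
    return float(KCAL_COULOMB * np.sum(np.outer(q[rec], q[lig]) / r))


def lj_energy(structure: Structure, partition: BindingPartition, coords=None) -> float:
    """Cross-partition 12-6 Lennard-Jones energy (Lorentz–Berthelot combining)."""
    pos = _coords(structure, coords)
    rec, lig = partition.masks(structure)
    r = _cross_distances(pos, rec, lig)
    sig = 0.5 * (structure.lj_sigma[rec][:, None] + structure.lj_sigma[lig][None, :])
    eps = np.sqrt(structure.lj_epsilon[rec][:, None] * structure.lj_epsilon[lig][None, :])
    sr6 = (sig / r) ** 6
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))


def gb_polar_energy(
    structure: Structure,
    mask=None,
    coords=None,
    eps_in: float = 1.0,
    eps_out: float = 80.0,
) -> float:
    """Pairwise generalized-Born polar solvation energy of an atom set.

    ΔG_pol = −½·k_e·(1/ε_in − 1/ε_out)·Σ_ij q_i q_j / f_GB with
    f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))); the i = j self terms
    (f_GB = R_i) give the Born self-energies.
    """
    pos = _coords(structure, coords)
    if mask is None:
        mask = np.ones(len(structure), bool)
    mask = np.asarray(mask, bool)
    q = structure.charges[mask]
    R = structure.born_radii[mask]
    if np.any(R <= 0):
        raise EnergyError("Born radii must be positive")
    if len(q) == 0 or not np.any(q):
        return 0.0
    p = pos[mask]
    r2 = cdist(p, p, "sqeuclidean")
    RiRj = np.outer(R, R)
    f = np.sqrt(r2 + RiRj * np.exp(-r2 / (4.0 * RiRj)))
    pref = -0.5 * KCAL_COULOMB * (1.0 / eps_in - 1.0 / eps_out)
    return float(pref * np.sum(np.outer(q, q) / f))


_POINT_CACHE: dict = {}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere points (golden-spiral lattice)."""
    if n not in _POINT_CACHE:
        i = np.arange(n) + 0.5
        phi = np.arccos(1.0 - 2.0 * i / n)
        theta = np.pi * (1.0 + 5.0**0.5) * i
        _POINT_CACHE[n] = np.stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
        )
    return _POINT_CACHE[n]


def sasa(
    positions: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 256,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point counting.

    Each atom's solvent sphere (radius r_i + probe) is sampled with a fixed
    golden-spiral lattice of ``n_points`` points; points buried inside any
    neighbour's solvent sphere are discarded. Deterministic for a fixed
    lattice size; quadrature error shrinks as 1/n_points.
    """
    if n_points < 32:
        raise EnergyError("n_points must be at least 32")
    positions = np.asarray(positions, float)
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise EnergyError("radii must be positive")
    n = len(positions)
    ext = radii + probe
    pts = _sphere_points(n_points)
    areas = np.empty(n)
    d = cdist(positions, positions)
    for i in range(n):
        neigh = np.nonzero((d[i] < ext[i] + ext) & (np.arange(n) != i))[0]
        sphere = positions[i] + ext[i] * pts
        if len(neigh):
            dist2 = cdist(sphere, positions[neigh], "sqeuclidean")
            buried = (dist2 < (ext[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return areas


def binding_energy(
    structure: Structure,
    partition: BindingPartition,
    params: EnergyParams = EnergyParams(),
    coords=None,
) -> EnergyComponents:
    """Single-trajectory end-point binding energy of one snapshot.

    vdW and electrostatic terms are cross-partition pair sums (intra-state
    terms cancel identically when complex, receptor and ligand share
    coordinates); polar and nonpolar solvation are complex − receptor −
    ligand differences.
    """
    pos = _coords(structure, coords)
    rec, lig = partition.masks(structure)
    if not rec.any():
        raise EnergyError("empty receptor side of the binding partition")
    vdw = lj_energy(structure, partition, pos)
    ele = coulomb_energy(structure, partition, pos)

    both = rec | lig
    gb = lambda m: gb_polar_energy(structure, m, pos, params.eps_in, params.eps_out)
    gb_polar = gb(both) - gb(rec) - gb(lig)

    def nonpolar_of(mask):
        a = sasa(pos[mask], structure.born_radii[mask], params.probe_radius, params.sasa_points)
        return params.gamma * a.sum() + params.beta

    nonpolar = nonpolar_of(both) - nonpolar_of(rec) - nonpolar_of(lig)
    return EnergyComponents.from_parts(vdw, ele, gb_polar, nonpolar)


def trajectory_energies(
    trajectory: Trajectory,
    partition: BindingPartition,
    params: EnergyParams = EnergyParams(),
    replicate: int = 0,
):
    """Per-frame binding-energy components for a whole trajectory (DataFrame)."""
    import pandas as pd

    rows = []
    for f in range(trajectory.n_frames):
        ec = binding_energy(trajectory.structure, partition, params, trajectory.coords[f])
        rows.append((replicate, f, ec.vdw, ec.ele, ec.gb_polar, ec.nonpolar, ec.total))
    return pd.DataFrame(
        rows, columns=["replicate", "frame", "vdw", "ele", "gb_polar", "nonpolar", "total"]
    )


# --------------------------------------------------------------------------
# Water mobility
# --------------------------------------------------------------------------

B_FACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


def _atom_b_factors(coords: np.ndarray) -> np.ndarray:
    """B = (8π²/3)·⟨|r − ⟨r⟩|²⟩ per atom from (frames, atoms, 3) coordinates."""
    mean = coords.mean(axis=0, keepdims=True)
    msd = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)
    return B_FACTOR_PREFACTOR * msd


def water_b_factor(trajectory: Trajectory) -> dict[int, float]:
    """Positional B-factor per water residue (Å²), about the time-mean position.

    Deviations are taken from each atom's own time mean, so a constant offset
    applied to every frame leaves B unchanged. Requires at least 10 frames.
    """
    if trajectory.n_frames < 10:
        raise EnergyError("need at least 10 frames for B-factor estimation")
    s = trajectory.structure
    out: dict[int, float] = {}
    wat = s.entity_mask({"water"})
    b = _atom_b_factors(trajectory.coords)
    for resid in sorted(set(s.residue_indices[wat])):
        m = wat & (s.residue_indices == resid)
        out[int(resid)] = float(b[m].mean())
    return out


def protein_b_factors(trajectory: Trajectory) -> np.ndarray:
    """Per-atom B-factors of the protein entity."""
    if trajectory.n_frames < 10:
        raise EnergyError("need at least 10 frames for B-factor estimation")
    mask = trajectory.structure.entity_mask({"protein"})
    return _atom_b_factors(trajectory.coords[:, mask, :])


def select_key_waters(trajectory: Trajectory, kappa: float = 1.25) -> list[int]:
    """Water residues whose B-factor is comparable to the protein's atoms.

    Keeps waters with B ≤ κ·median(protein-atom B); returns residue indices
    sorted by B ascending (most ordered first). Such waters do not exchange
    with bulk solvent and are treated as structural parts of the ligand.
    """
    wb = water_b_factor(trajectory)
    if not wb:
        return []
    pb = protein_b_factors(trajectory)
    if len(pb) == 0:
        warnings.warn("no protein atoms; key-water selection returns nothing")
        return []
    threshold = kappa * float(np.median(pb))
    kept = [(b, rid) for rid, b in wb.items() if b <= threshold]
    return [rid for _, rid in sorted(kept)]
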