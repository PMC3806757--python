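"""Synthetic inputs with known ground truth.

Three generators cover everything the analysis pipeline consumes:

* :func:`gen_energy_series` — per-frame binding-energy component series with a
  hidden Markov-switching macrostate structure, emulating the multi-replicate
  MM-GBSA time series whose subpopulation statistics the reference table
  records.
* :func:`gen_toy_complex` — a desk-scale binding pocket (protein shell, ligand,
  optional divalent ions with octahedral coordination cages, conserved "key"
  waters and mobile bulk waters) plus a jittered trajectory.
* :func:`gen_dihedral_series` — circular samples from gauche−/trans/gauche+
  style rotamer clusters.

All randomness flows through one ``numpy`` Generator seeded from the config, so
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import (
    Atom,
    BORN_RADII,
    LJ_EPSILON,
    LJ_SIGMA,
    Structure,
    Trajectory,
)

COMPONENTS = ("vdw", "ele", "gb_polar", "nonpolar")
ENERGY_COLUMNS = ("replicate", "frame", "vdw", "ele", "gb_polar", "nonpolar", "total")


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its geometric constraints."""


# --------------------------------------------------------------------------
# Markov-switching energy series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpec:
    """One macrostate: component means/SDs (kcal/mol), occupancy, total SD.

    ``total_sd`` is the standard deviation of the *total* energy within the
    state. In end-point rescoring the electrostatic and polar-solvation
    components fluctuate in near-perfect anticorrelation, so the total is far
    quieter than the quadrature sum of the component SDs; the generator honors
    the total SD exactly and treats the component SDs as marginal targets
    (see :func:`gen_energy_series`). When omitted it falls back to the
    independent-component quadrature sum.
    """

    label: str
    component_means: tuple[float, float, float, float]
    component_sds: tuple[float, float, float, float]
    occupancy: float
    total_sd: float | None = None

    def __post_init__(self):
        if len(self.component_means) != 4 or len(self.component_sds) != 4:
            raise ValueError("component_means and component_sds must have 4 entries")
        if any(s < 0 for s in self.component_sds):
            raise ValueError("component SDs must be non-negative")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError("occupancy must lie in (0, 1]")
        if self.total_sd is not None and self.total_sd < 0:
            raise ValueError("total_sd must be non-negative")

    @property
    def total_mean(self) -> float:
        return float(sum(self.component_means))

    def effective_total_sd(self) -> float:
        if self.total_sd is not None:
            return float(self.total_sd)
        return float(np.sqrt(np.sum(np.square(self.component_sds))))

    @classmethod
    def from_reference_row(cls, row) -> "StateSpec":
        """Build a state from one row of the bundled reference table."""
        return cls(
            label=str(row["mode"]),
            component_means=(row["vdw_mean"], row["ele_mean"], row["gb_mean"], row["np_mean"]),
            component_sds=(row["vdw_sd"], row["ele_sd"], row["gb_sd"], row["np_sd"]),
            occupancy=float(row["occupancy_pct"]) / 100.0,
            total_sd=float(row["total_sd"]),
        )


@dataclass(frozen=True)
class GeneratorConfig:
    states: tuple[StateSpec, ...]
    n_replicates: int = 3
    n_frames: int = 5000
    mean_dwell: float = 50.0
    frame_interval_ps: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not self.states:
            raise ValueError("at least one state required")
        occ = sum(s.occupancy for s in self.states)
        if abs(occ - 1.0) > 1e-9:
            raise ValueError(f"state occupancies must sum to 1 (got {occ:.12f})")
        if self.n_replicates < 1 or self.n_frames < 1:
            raise ValueError("n_replicates and n_frames must be positive")
        if self.mean_dwell <= 1:
            raise ValueError("mean_dwell must exceed 1 frame")
        if self.n_frames < 10 * len(self.states):
            raise ValueError("n_frames must be at least 10x the number of states")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([s.occupancy for s in self.states], float)

    @classmethod
    def from_states(cls, states: Sequence[StateSpec], *, normalize: bool = True, **kw):
        """Build a config, optionally renormalizing occupancies (printed
        occupancy columns sum to 99.7–100.0 after rounding)."""
        states = list(states)
        if normalize:
            tot = sum(s.occupancy for s in states)
            states = [
                StateSpec(s.label, s.component_means, s.component_sds, s.occupancy / tot, s.total_sd)
                for s in states
            ]
        return cls(states=tuple(states), **kw)


@dataclass
class GroundTruth:
    """Hidden-state paths and the requested per-state statistics."""

    state_labels: list
    state_paths: list          # one int array per replicate
    true_occupancies: np.ndarray
    true_component_means: np.ndarray   # (n_states, 4)
    true_total_means: np.ndarray
    true_total_sds: np.ndarray

    def empirical_occupancies(self) -> np.ndarray:
        counts = np.zeros(len(self.state_labels))
        total = 0
        for path in self.state_paths:
            counts += np.bincount(path, minlength=len(self.state_labels))
            total += len(path)
        return counts / total


def markov_from_occupancies(occupancies: Sequence[float], mean_dwell: float) -> np.ndarray:
    """Row-stochastic transition matrix with stationary distribution exactly
    equal to ``occupancies``.

    The chain is built from an embedded jump chain ``J_ij = π_j / (1 − π_i)``
    (jump targets weighted by occupancy) with per-state mean dwell
    ``d_i = mean_dwell · π_i / φ_i`` where φ is the stationary distribution of
    J. The visit-averaged dwell equals ``mean_dwell``; for equal occupancies
    every diagonal entry is exactly ``1 − 1/mean_dwell``. A constant diagonal
    with exact stationarity is infeasible whenever one occupancy exceeds ½, so
    dominant states dwell proportionally longer — matching the long residence
    in the dominant binding mode seen in the reference trajectories.
    """
    pi = np.asarray(occupancies, float)
    if np.any(pi <= 0):
        raise ValueError("occupancies must be positive")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError(f"occupancies must sum to 1 (got {pi.sum():.12f})")
    if mean_dwell <= 1:
        raise ValueError("mean_dwell must exceed 1 frame")
    n = len(pi)
    if n == 1:
        return np.array([[1.0]])
    J = pi[None, :] / (1.0 - pi[:, None])
    np.fill_diagonal(J, 0.0)
    J /= J.sum(axis=1, keepdims=True)  # guard rounding
    phi = _stationary(J)
    dwell = mean_dwell * pi / phi
    if np.any(dwell <= 1):
        raise ValueError(
            "mean_dwell too short to realize these occupancies; increase mean_dwell"
        )
    P = J / dwell[:, None]
    np.fill_diagonal(P, 1.0 - 1.0 / dwell)
    return P


def _stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (linear solve)."""
    n = P.shape[0]
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


def _simulate_path(P: np.ndarray, pi: np.ndarray, n_frames: int, rng) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    path = np.empty(n_frames, dtype=int)
    state = int(np.searchsorted(np.cumsum(pi), rng.random()))
    u = rng.random(n_frames)
    for t in range(n_frames):
        path[t] = state
        state = int(np.searchsorted(cum[state], u[t]))
    return path


def _sample_components(state: StateSpec, n: int, rng) -> np.ndarray:
    """Component draws (n, 4) whose row sums have SD exactly state.total_sd.

    Independent per-component deviations are conditioned on their sum: the sum
    deviation is replaced by a draw from N(0, total_sd²), allocated across
    components in proportion to their variances. Component means are exact in
    expectation; marginal component SDs shrink somewhat relative to the
    nominal values whenever total_sd is far below their quadrature sum (the
    strongly anticorrelated regime).
    """
    mu = np.array(state.component_means, float)
    sd = np.array(state.component_sds, float)
    s2 = sd**2
    S = s2.sum()
    if S == 0.0:
        return np.tile(mu, (n, 1))
    z = rng.normal(0.0, sd, size=(n, 4))
    t = rng.normal(0.0, state.effective_total_sd(), size=n)
    adjust = (t - z.sum(axis=1))[:, None] * (s2 / S)[None, :]
    return mu[None, :] + z + adjust


def gen_energy_series(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate replicate energy-component series with hidden macrostates.

    Returns a DataFrame with columns ``replicate, frame, vdw, ele, gb_polar,
    nonpolar, total`` (``total`` is the exact per-frame component sum) and the
    generating ground truth.
    """
    rng = np.random.default_rng(config.seed)
    P = markov_from_occupancies(config.occupancies, config.mean_dwell)
    pi = config.occupancies
    frames = np.arange(config.n_frames)
    paths, blocks = [], []
    for rep in range(config.n_replicates):
        path = _simulate_path(P, pi, config.n_frames, rng)
        comp = np.empty((config.n_frames, 4))
        for k, state in enumerate(config.states):
            idx = np.nonzero(path == k)[0]
            if idx.size:
                comp[idx] = _sample_components(state, idx.size, rng)
        block = pd.DataFrame(comp, columns=list(COMPONENTS))
        block.insert(0, "frame", frames)
        block.insert(0, "replicate", rep)
        block["total"] = block[list(COMPONENTS)].sum(axis=1)
        paths.append(path)
        blocks.append(block)
    df = pd.concat(blocks, ignore_index=True)
    truth = GroundTruth(
        state_labels=[s.label for s in config.states],
        state_paths=paths,
        true_occupancies=pi.copy(),
        true_component_means=np.array([s.component_means for s in config.states], float),
        true_total_means=np.array([s.total_mean for s in config.states]),
        true_total_sds=np.array([s.effective_total_sd() for s in config.states]),
    )
    return df, truth


# --------------------------------------------------------------------------
# Toy complexes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyComplexSpec:
    """Layout parameters for a toy binding pocket.

    ``contact_residues`` point their (positively charged) side-chain tips into
    the pocket toward the uniformly negative ligand; all other side chains
    point outward and carry negligible charge, so only designated residues
    interact appreciably with the ligand. Each ion sits in a rigid octahedral
    cage of six oxygens at 2.1 Å, filled by key waters, two dedicated ligand
    oxygens and carboxylate-like oxygens of ``acidic_residues``. Thermal
    amplitudes are per-axis Gaussian σ in Å; key waters move far less than
    bulk waters by construction.
    """

    n_residues: int = 12
    contact_residues: tuple[int, ...] = (0, 1, 2)
    acidic_residues: tuple[int, ...] = (3, 4)
    sidechain_atoms: int = 3
    ligand_atoms: int = 8
    ligand_atom_charge: float = -0.125
    contact_tip_charge: float = 0.40
    n_ions: int = 2
    n_key_waters: int = 3
    n_bulk_waters: int = 30
    n_frames: int = 200
    pocket_radius: float = 11.0
    amp_protein: float = 0.15
    amp_ligand: float = 0.10
    amp_ion: float = 0.05
    amp_key_water: float = 0.10
    amp_bulk_water: float = 1.00
    frame_interval_ps: float = 10.0
    min_separation: float = 1.0
    max_retries: int = 20

    def __post_init__(self):
        if self.n_residues < 1 or self.ligand_atoms < 1:
            raise ValueError("need at least one residue and one ligand atom")
        if any(i >= self.n_residues for i in self.contact_residues + self.acidic_residues):
            raise ValueError("designated residue index out of range")
        if self.amp_key_water >= self.amp_bulk_water:
            raise ValueError("key waters must be less mobile than bulk waters")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


_OCTAHEDRON = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
)


def gen_toy_complex(spec: ToyComplexSpec, seed: int = 0) -> tuple[Structure, Trajectory]:
    """Build a toy complex and a jittered trajectory around it.

    The returned trajectory carries ground-truth bookkeeping in
    ``trajectory.meta`` (key-water residue indices, contact residues).
    """
    rng = np.random.default_rng(seed)
    for attempt in range(spec.max_retries):
        structure, amps, meta = _build_layout(spec, rng, rotation=0.37 * attempt)
        d = _min_pairwise_distance(structure.positions)
        if d >= spec.min_separation:
            break
    else:
        raise GenerationError(
            f"could not place atoms with min separation {spec.min_separation} Å "
            f"after {spec.max_retries} attempts"
        )
    jitter = rng.normal(0.0, 1.0, size=(spec.n_frames, len(structure), 3))
    coords = structure.positions[None, :, :] + jitter * amps[None, :, None]
    traj = Trajectory(structure, coords, frame_interval_ps=spec.frame_interval_ps, meta=meta)
    return structure, traj


def _min_pairwise_distance(pos: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    if len(pos) < 2:
        return np.inf
    return float(pdist(pos).min())


def _build_layout(
    spec: ToyComplexSpec, rng, rotation: float = 0.0
) -> tuple[Structure, np.ndarray, dict]:
    atoms: list[Atom] = []
    amps: list[float] = []
    next_id = [1]
    next_res = [1]

    def add(name, element, resname, entity, pos, charge, amp, roles=(), resid=None):
        if resid is None:
            resid = next_res[0]
        atoms.append(
            Atom(
                atom_id=next_id[0],
                name=name,
                element=element,
                residue_index=resid,
                residue_name=resname,
                entity=entity,
                position=tuple(float(x) for x in pos),
                charge=float(charge),
                lj_sigma=LJ_SIGMA[element],
                lj_epsilon=LJ_EPSILON[element],
                born_radius=BORN_RADII[element],
                hbond_roles=frozenset(roles),
            )
        )
        amps.append(amp)
        next_id[0] += 1
        return atoms[-1]

    # --- ligand: ring of uniformly charged atoms in the z=0 plane
    lig_res = next_res[0]
    ring = 2.0 * np.stack(
        [
            np.cos(2 * np.pi * np.arange(spec.ligand_atoms) / spec.ligand_atoms),
            np.sin(2 * np.pi * np.arange(spec.ligand_atoms) / spec.ligand_atoms),
            np.zeros(spec.ligand_atoms),
        ],
        axis=1,
    )
    for k, pos in enumerate(ring):
        element = "O" if k % 3 == 0 else ("N" if k % 3 == 1 else "C")
        roles = {"acceptor"} if element in ("O", "N") else set()
        add(f"L{k+1}", element, "LIG", "ligand", pos, spec.ligand_atom_charge, spec.amp_ligand, roles)
    next_res[0] += 1

    # --- ions with octahedral cages
    key_water_residues: list[int] = []
    n_key_left = spec.n_key_waters
    ion_centers = [np.array([0.0, 0.0, 3.0]), np.array([0.0, 0.0, -3.0])][: spec.n_ions]
    acidic_pool = list(spec.acidic_residues)
    acidic_ctr = [0]
    for i, center in enumerate(ion_centers):
        add(f"MG{i+1}", "MG", "MG", "ion", center, 2.0, spec.amp_ion)
        next_res[0] += 1
        vertices = center + 2.1 * _OCTAHEDRON
        # vertex roles: ±x lateral → key waters (near the ligand; fall back to
        # carboxylate oxygens), ±y lateral and the ligand-facing polar vertex →
        # dedicated ligand oxygens (phosphate-like, so their close ring contacts
        # stay intra-ligand), outward polar vertex → carboxylate-like protein
        # oxygen of an acidic residue (the Asp-coordination motif)
        inner_polar = 5 if center[2] > 0 else 4  # vertex pointing at the ligand plane
        for j in range(6):
            v = vertices[j]
            ligand_vertex = j in (2, 3) or j == inner_polar
            if n_key_left > 0 and j in (0, 1):
                resid = next_res[0]
                add("O", "O", "HOH", "water", v, -0.4, spec.amp_key_water,
                    {"donor_heavy", "acceptor"}, resid=resid)
                key_water_residues.append(resid)
                next_res[0] += 1
                n_key_left -= 1
            elif ligand_vertex:
                add(f"LO{i+1}{j}", "O", "LIG", "ligand", v, -0.40, spec.amp_ligand,
                    {"acceptor"}, resid=lig_res)
            else:
                if acidic_pool:
                    resid = 1000 + acidic_pool[acidic_ctr[0] % len(acidic_pool)]
                    acidic_ctr[0] += 1
                else:
                    resid = next_res[0]
                    next_res[0] += 1
                add(f"OD{i+1}{j}", "O", "ASP", "protein", v, -0.40, spec.amp_protein,
                    {"acceptor"}, resid=resid)
    # leftover key waters (e.g. no ions): circle 3.5 Å from the ligand center
    for k in range(n_key_left):
        ang = 2 * np.pi * k / max(n_key_left, 1)
        pos = np.array([2.4 * np.cos(ang), 2.4 * np.sin(ang), 1.8])
        resid = next_res[0]
        add("O", "O", "HOH", "water", pos, -0.4, spec.amp_key_water,
            {"donor_heavy", "acceptor"}, resid=resid)
        key_water_residues.append(resid)
        next_res[0] += 1

    # --- protein shell; contact residues take equatorial directions (clear of
    # the polar ion cages), the rest the quasi-uniform sphere lattice
    directions = _fibonacci_sphere(spec.n_residues)
    rot = np.array(
        [[np.cos(rotation), -np.sin(rotation), 0.0],
         [np.sin(rotation), np.cos(rotation), 0.0],
         [0.0, 0.0, 1.0]]
    )
    directions = directions @ rot.T
    n_contact = max(len(spec.contact_residues), 1)
    for m, r in enumerate(sorted(spec.contact_residues)):
        phi = 2.0 * np.pi * m / n_contact + 0.35 + rotation
        u = np.array([np.cos(phi), np.sin(phi), 0.12])
        directions[r] = u / np.linalg.norm(u)
    for r in range(spec.n_residues):
        u = directions[r]
        ca = spec.pocket_radius * u
        # local frame
        t = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(t) < 1e-8:
            t = np.cross(u, [0.0, 1.0, 0.0])
        t /= np.linalg.norm(t)
        w = np.cross(u, t)
        resid = 1000 + r
        resname = "CNT" if r in spec.contact_residues else ("ASP" if r in spec.acidic_residues else "RES")
        is_contact = r in spec.contact_residues
        add("N", "N", resname, "protein", ca + 1.45 * t, -0.10, spec.amp_protein,
            {"donor_heavy"}, resid=resid)
        add("CA", "C", resname, "protein", ca, 0.05, spec.amp_protein, resid=resid)
        add("C", "C", resname, "protein", ca - 1.50 * t, 0.15, spec.amp_protein, resid=resid)
        add("O", "O", resname, "protein", ca - 1.50 * t + 1.23 * w, -0.10, spec.amp_protein,
            {"acceptor"}, resid=resid)
        inward = -u if is_contact else u
        add("CB", "C", resname, "protein", ca + 1.53 * inward, 0.0, spec.amp_protein, resid=resid)
        for k in range(spec.sidechain_atoms):
            dist = 1.53 + 1.33 * (k + 1)
            tip = k == spec.sidechain_atoms - 1
            q = (spec.contact_tip_charge if is_contact else 0.02) if tip else 0.0
            elem = "N" if (tip and is_contact) else "C"
            roles = {"donor_heavy"} if (tip and is_contact) else set()
            add(f"SC{k+1}", elem, resname, "protein", ca + dist * inward, q, spec.amp_protein,
                roles, resid=resid)

    # --- bulk waters on an outer shell (seeded scatter)
    shell = _fibonacci_sphere(max(spec.n_bulk_waters, 1))
    for k in range(spec.n_bulk_waters):
        pos = shell[k] * (17.0 + 2.0 * rng.random()) + rng.normal(0, 0.3, 3)
        resid = next_res[0]
        add("O", "O", "HOH", "water", pos, -0.4, spec.amp_bulk_water,
            {"donor_heavy", "acceptor"}, resid=resid)
        next_res[0] += 1

    structure = Structure(atoms)
    meta = {
        "key_water_residues": key_water_residues,
        "contact_residues": [1000 + r for r in spec.contact_residues],
        "acidic_residues": [1000 + r for r in spec.acidic_residues],
    }
    return structure, np.array(amps), meta


# --------------------------------------------------------------------------
# Dihedral series
# --------------------------------------------------------------------------

def wrap_angle_deg(x) -> np.ndarray | float:
    """Wrap angles to (−180°, 180°]."""
    y = -((-np.asarray(x, float) + 180.0) % 360.0 - 180.0)
    return y if np.ndim(x) else float(y)


@dataclass(frozen=True)
class DihedralClusterSpec:
    """Mixture of von Mises rotamer clusters (centers in degrees)."""

    centers_deg: tuple[float, ...] = (-60.0, 180.0, 60.0)
    kappas: tuple[float, ...] = (20.0, 20.0, 20.0)
    weights: tuple[float, ...] = (0.25, 0.5, 0.25)
    n_samples: int = 5000
    name: str = "chi"

    def __post_init__(self):
        if not (len(self.centers_deg) == len(self.kappas) == len(self.weights)):
            raise ValueError("centers, kappas and weights must have equal length")
        if any(not (-180.0 < c <= 180.0) for c in self.centers_deg):
            raise ValueError("cluster centers must lie in (−180°, 180°]")
        if any(k <= 0 for k in self.kappas):
            raise ValueError("concentrations must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("cluster weights must sum to 1")


def gen_dihedral_series(spec: DihedralClusterSpec, seed: int = 0):
    """Sample a wrapped dihedral series from the cluster mixture."""
    from .interactions import DihedralSeries

    rng = np.random.default_rng(seed)
    comp = rng.choice(len(spec.weights), size=spec.n_samples, p=spec.weights)
    mu = np.radians(np.asarray(spec.centers_deg))[comp]
    kappa = np.asarray(spec.kappas)[comp]
    values = wrap_angle_deg(np.degrees(rng.vonmises(mu, kappa)))
    return DihedralSeries(name=spec.name, atom_quadruple=(0, 0, 0, 0), values=values)


def circular_mean_deg(values) -> float:
    """Circular mean of angles in degrees, result in (−180°, 180°]."""
    rad = np.radians(np.asarray(values, float))
    return float(wrap_angle_deg(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))))
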