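"""Atomic containers for toy protein–ligand complexes.

The package works on desk-scale model complexes: every atom carries the
quantities the energy engine needs (partial charge, 12-6 Lennard-Jones
parameters, a fixed Born radius) plus bookkeeping for residue membership,
entity class (protein / ligand / water / ion) and hydrogen-bonding roles.
Coordinates are in Å, charges in elementary units, energies downstream in
kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

ENTITIES = ("protein", "ligand", "water", "ion")
HBOND_ROLES = ("donor_heavy", "acceptor", "hydrogen")

#: fixed per-element Born radii (Å); deterministic stand-in for effective-radii
#: integration, keeps the GB term pairwise and exactly testable
BORN_RADII = {
    "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.5,
    "P": 1.85, "S": 1.8, "MG": 1.45, "NA": 1.6, "CL": 1.8,
}

#: per-element 12-6 parameters (σ in Å, ε in kcal/mol) used by the toy builder
LJ_SIGMA = {"H": 2.5, "C": 3.4, "N": 3.25, "O": 3.0, "P": 3.7, "S": 3.6, "MG": 1.9}
LJ_EPSILON = {"H": 0.02, "C": 0.10, "N": 0.17, "O": 0.20, "P": 0.20, "S": 0.25, "MG": 0.875}


class StructureError(ValueError):
    """Raised for malformed structures or invalid atom parameters."""


@dataclass(frozen=True)
class Atom:
    atom_id: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    entity: str
    position: tuple[float, float, float]
    charge: float = 0.0
    lj_sigma: float = 3.4
    lj_epsilon: float = 0.1
    born_radius: float = 1.7
    hbond_roles: frozenset = frozenset()

    def __post_init__(self):
        if self.entity not in ENTITIES:
            raise StructureError(f"unknown entity {self.entity!r} for atom {self.atom_id}")
        if self.born_radius <= 0:
            raise StructureError(f"atom {self.atom_id}: born_radius must be > 0")
        if self.lj_sigma <= 0:
            raise StructureError(f"atom {self.atom_id}: lj_sigma must be > 0")
        bad = set(self.hbond_roles) - set(HBOND_ROLES)
        if bad:
            raise StructureError(f"atom {self.atom_id}: unknown h-bond roles {sorted(bad)}")


class Structure:
    """Ordered atom collection with cached numpy views of the per-atom fields."""

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        ids = [a.atom_id for a in atoms]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StructureError(f"duplicate atom_ids: {dupes}")
        self.atoms = atoms
        self._rebuild()

    def _rebuild(self) -> None:
        n = len(self.atoms)
        self.positions = np.array([a.position for a in self.atoms], float).reshape(n, 3)
        self.charges = np.array([a.charge for a in self.atoms], float)
        self.lj_sigma = np.array([a.lj_sigma for a in self.atoms], float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms], float)
        self.born_radii = np.array([a.born_radius for a in self.atoms], float)
        self.entities = np.array([a.entity for a in self.atoms], dtype=object)
        self.residue_indices = np.array([a.residue_index for a in self.atoms], int)
        self.atom_ids = np.array([a.atom_id for a in self.atoms], int)

    def __len__(self) -> int:
        return len(self.atoms)

    def __eq__(self, other) -> bool:
        return isinstance(other, Structure) and self.atoms == other.atoms

    def entity_mask(self, entities: Iterable[str]) -> np.ndarray:
        entities = set(entities)
        return np.array([a.entity in entities for a in self.atoms], bool)

    def subset(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask, bool)
        return Structure([a for a, keep in zip(self.atoms, mask) if keep])

    def with_positions(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError(f"coordinate shape {coords.shape} does not match atom count")
        return Structure([replace(a, position=tuple(xyz)) for a, xyz in zip(self.atoms, coords)])

    def atom_by_id(self, atom_id: int) -> Atom:
        for a in self.atoms:
            if a.atom_id == atom_id:
                return a
        raise KeyError(f"no atom with id {atom_id}")

    def index_of(self, atom_id: int) -> int:
        hits = np.nonzero(self.atom_ids == atom_id)[0]
        if len(hits) == 0:
            raise KeyError(f"no atom with id {atom_id}")
        return int(hits[0])

    def residues(self, entity: str | None = None) -> list[tuple[int, str]]:
        seen: dict[int, str] = {}
        for a in self.atoms:
            if entity is None or a.entity == entity:
                seen.setdefault(a.residue_index, a.residue_name)
        return sorted(seen.items())


@dataclass
class Trajectory:
    """A static structure plus per-frame coordinates (frames × atoms × 3, Å)."""

    structure: Structure
    coords: np.ndarray
    frame_interval_ps: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.structure), 3):
            raise StructureError(
                f"trajectory coords shape {self.coords.shape} does not match structure "
                f"({len(self.structure)} atoms)"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def timestamps_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps


@dataclass(frozen=True)
class BindingPartition:
    """Receptor/ligand split of a complex for single-trajectory end-point scoring.

    Waters are bulk (excluded) by default; key waters are pulled onto the ligand
    side by residue index, mirroring the natural-ligand definition that bundles
    the nucleotide with its ions and conserved waters.
    """

    ligand_entities: frozenset = frozenset({"ligand", "ion"})
    receptor_entities: frozenset = frozenset({"protein"})
    ligand_water_residues: frozenset = frozenset()

    def __post_init__(self):
        if self.ligand_entities & self.receptor_entities:
            raise StructureError("receptor and ligand entity sets must be disjoint")

    def masks(self, structure: Structure) -> tuple[np.ndarray, np.ndarray]:
        """Return (receptor_mask, ligand_mask); unassigned waters fall in neither."""
        lig = structure.entity_mask(self.ligand_entities)
        rec = structure.entity_mask(self.receptor_entities)
        if self.ligand_water_residues:
            wat = structure.entity_mask({"water"})
            keyw = wat & np.isin(structure.residue_indices, sorted(self.ligand_water_residues))
            lig = lig | keyw
        if not lig.any():
            raise StructureError("empty ligand side of the binding partition")
        return rec, lig
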