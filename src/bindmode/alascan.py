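"""Computational alanine scanning per macrostate.

Each protein residue is truncated to alanine (all side-chain atoms beyond Cβ
removed, everything else untouched — the local-perturbation assumption: no
re-minimization, no charge redistribution) and the snapshot is rescored with
the end-point energy engine. The per-residue contribution is

    ΔΔG = ΔG_mut − ΔG_wt,

averaged over the snapshots of one macrostate; a residue that stabilizes
binding loses favourable interactions on truncation, giving ΔΔG > 0.
Glycine and alanine have nothing beyond Cβ and are reported as 0 with a
not-mutated flag. Waters are stripped before scanning except the key waters
that belong to the ligand partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .energetics import EnergyError, EnergyParams, binding_energy
from .structures import BindingPartition, Structure, Trajectory

#: atoms kept by the truncation: backbone plus Cβ and their hydrogens
BACKBONE_KEEP = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA1", "HA2", "HA3", "CB"}
NOT_MUTATED = {"GLY", "ALA"}


class MutationError(ValueError):
    """Raised when a residue cannot be mutated."""


@dataclass(frozen=True)
class ResidueContribution:
    residue_index: int
    residue_name: str
    macrostate_label: str
    ddg_mean: float
    ddg_sd: float
    n_snapshots: int
    mutated: bool = True

    def __post_init__(self):
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")


def _is_kept(name: str) -> bool:
    return name in BACKBONE_KEEP or name.startswith("HB")


def alanine_mask(structure: Structure, residue_index: int) -> np.ndarray:
    """Boolean keep-mask implementing the truncation of one residue to alanine."""
    res_atoms = [
        a for a in structure.atoms if a.residue_index == residue_index and a.entity == "protein"
    ]
    if not res_atoms:
        entities = {
            a.entity for a in structure.atoms if a.residue_index == residue_index
        }
        if entities:
            raise MutationError(
                f"residue {residue_index} is not on the protein side (entity {sorted(entities)})"
            )
        raise MutationError(f"no residue with index {residue_index}")
    if res_atoms[0].residue_name == "PRO":
        warnings.warn("truncating proline like a generic residue (ring opened)")
    keep = np.ones(len(structure), bool)
    for i, a in enumerate(structure.atoms):
        if a.residue_index == residue_index and a.entity == "protein" and not _is_kept(a.name):
            keep[i] = False
    return keep


def mutate_to_alanine(structure: Structure, residue_index: int) -> Structure:
    """Truncate one protein residue to alanine; Gly/Ala come back unchanged."""
    name = dict(structure.residues()).get(residue_index)
    if name in NOT_MUTATED:
        return structure
    return structure.subset(alanine_mask(structure, residue_index))


def strip_waters(structure: Structure, keep_residues=()) -> np.ndarray:
    """Keep-mask removing water atoms except the listed water residues."""
    keep = np.ones(len(structure), bool)
    keep_residues = set(keep_residues)
    for i, a in enumerate(structure.atoms):
        if a.entity == "water" and a.residue_index not in keep_residues:
            keep[i] = False
    return keep


def alanine_scan(
    trajectory: Trajectory,
    frames,
    partition: BindingPartition,
    params: EnergyParams = EnergyParams(),
    stride: int = 1,
    macrostate_label: str = "",
    keep_key_waters: bool = True,
) -> list[ResidueContribution]:
    """Per-residue ΔΔG profile over the (strided) snapshots of one macrostate.

    ``frames`` are the frame indices belonging to the macrostate; every
    ``stride``-th of them is rescored. Bulk waters are removed before
    scanning; the partition's ligand-side key waters are retained when
    ``keep_key_waters`` (they are part of the scored complex).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = list(frames)[::stride]
    if not frames:
        raise EnergyError("no snapshots left after striding")

    base_keep = strip_waters(
        trajectory.structure,
        partition.ligand_water_residues if keep_key_waters else (),
    )
    base = trajectory.structure.subset(base_keep)
    coords = trajectory.coords[:, base_keep, :]

    wt = np.array(
        [binding_energy(base, partition, params, coords[f]).total for f in frames]
    )

    out = []
    for resid, resname in base.residues("protein"):
        if resname in NOT_MUTATED:
            out.append(
                ResidueContribution(resid, resname, macrostate_label, 0.0, 0.0,
                                    len(frames), mutated=False)
            )
            continue
        keep = alanine_mask(base, resid)
        if keep.all():  # nothing beyond Cβ even without the name convention
            out.append(
                ResidueContribution(resid, resname, macrostate_label, 0.0, 0.0,
                                    len(frames), mutated=False)
            )
            continue
        mut = base.subset(keep)
        ddg = np.array(
            [binding_energy(mut, partition, params, coords[f][keep]).total for f in frames]
        ) - wt
        out.append(
            ResidueContribution(resid, resname, macrostate_label,
                                float(ddg.mean()), float(ddg.std(ddof=0)), len(frames))
        )
    return out


def contributions_to_frame(contribs: list[ResidueContribution]):
    """Tabular view (pandas DataFrame) of a scan profile."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "residue_index": c.residue_index,
                "residue_name": c.residue_name,
                "macrostate": c.macrostate_label,
                "ddg_mean": c.ddg_mean,
                "ddg_sd": c.ddg_sd,
                "n_snapshots": c.n_snapshots,
                "mutated": c.mutated,
            }
            for c in contribs
        ]
    )
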