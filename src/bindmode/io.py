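"""File formats: PQR-style structures, compact text trajectories, CSV tables.

Structures use PDB-like ATOM records carrying partial charge and radius in
the trailing numeric columns (the PQR convention), with entity tags, plus a
sidecar CSV (``<stem>.params.csv``) holding element, Lennard-Jones parameters
and hydrogen-bond roles per atom. Positions round-trip at 3 decimals, charges
at 4.

Tabular outputs are CSV with a leading ``# key: value`` metadata block
(seed, parameters, config hash) so every artifact records how it was made.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import Atom, BORN_RADII, LJ_EPSILON, LJ_SIGMA, Structure, Trajectory


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".params.csv")


def write_structure(structure: Structure, path) -> None:
    path = Path(path)
    lines = ["REMARK generated by bindmode"]
    for a in structure.atoms:
        x, y, z = a.position
        lines.append(
            f"ATOM {a.atom_id:6d} {a.name:<5s} {a.residue_name:<4s} {a.residue_index:6d} "
            f"{x:10.3f} {y:10.3f} {z:10.3f} {a.charge:9.4f} {a.born_radius:7.3f}"
        )
    path.write_text("\n".join(lines) + "\n")
    side = pd.DataFrame(
        [
            {
                "atom_id": a.atom_id,
                "element": a.element,
                "entity": a.entity,
                "lj_sigma": a.lj_sigma,
                "lj_epsilon": a.lj_epsilon,
                "hbond_roles": "|".join(sorted(a.hbond_roles)),
            }
            for a in structure.atoms
        ]
    )
    side.to_csv(_sidecar(path), index=False)


def read_structure(path) -> Structure:
    path = Path(path)
    side = {}
    sc = _sidecar(path)
    if sc.exists():
        for row in pd.read_csv(sc, keep_default_na=False).to_dict("records"):
            side[int(row["atom_id"])] = row

    atoms, seen = [], {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        tok = line.split()
        if len(tok) != 10:
            raise ParseError(f"{path}:{ln}: malformed ATOM record ({len(tok)} fields)")
        try:
            atom_id = int(tok[1])
            name, resname = tok[2], tok[3]
            resid = int(tok[4])
            x, y, z = (float(v) for v in tok[5:8])
            charge, radius = float(tok[8]), float(tok[9])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from None
        if atom_id in seen:
            raise ParseError(f"{path}:{ln}: duplicate atom_id {atom_id} (first at line {seen[atom_id]})")
        seen[atom_id] = ln
        meta = side.get(atom_id, {})
        element = meta.get("element") or (name[:2] if name[:2] in BORN_RADII else name[0])
        roles = frozenset(r for r in str(meta.get("hbond_roles", "")).split("|") if r)
        atoms.append(
            Atom(
                atom_id=atom_id,
                name=name,
                element=element,
                residue_index=resid,
                residue_name=resname,
                entity=meta.get("entity", "protein"),
                position=(x, y, z),
                charge=charge,
                lj_sigma=float(meta.get("lj_sigma", LJ_SIGMA.get(element, 3.4))),
                lj_epsilon=float(meta.get("lj_epsilon", LJ_EPSILON.get(element, 0.1))),
                born_radius=radius,
                hbond_roles=roles,
            )
        )
    if not atoms:
        raise ParseError(f"{path}: no ATOM records (empty structure)")
    return Structure(atoms)


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Compact text trajectory: MODEL blocks of xyz rows in structure order."""
    path = Path(path)
    out = [f"# frames={trajectory.n_frames} atoms={len(trajectory.structure)} "
           f"interval_ps={trajectory.frame_interval_ps}"]
    for f in range(trajectory.n_frames):
        out.append(f"MODEL {f}")
        out.extend(
            f"{x:.4f} {y:.4f} {z:.4f}" for x, y, z in trajectory.coords[f]
        )
        out.append("ENDMDL")
    path.write_text("\n".join(out) + "\n")


def read_trajectory(path, structure: Structure) -> Trajectory:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ParseError(f"{path}:1: missing trajectory header")
    header = dict(kv.split("=") for kv in lines[0][1:].split())
    interval = float(header.get("interval_ps", 10.0))
    frames, current = [], None
    for ln, line in enumerate(lines[1:], start=2):
        if line.startswith("MODEL"):
            current = []
        elif line.startswith("ENDMDL"):
            if current is None:
                raise ParseError(f"{path}:{ln}: ENDMDL without MODEL")
            frames.append(current)
            current = None
        elif line.strip() and current is not None:
            current.append([float(v) for v in line.split()])
    coords = np.array(frames, float)
    return Trajectory(structure, coords, frame_interval_ps=interval)


# --------------------------------------------------------------------------
# Tables with metadata headers
# --------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition(":")
            meta[k.strip()] = v.strip()
    return meta


def write_energy_csv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    write_table(df, path, metadata)


def read_energy_csv(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"replicate", "frame", "vdw", "ele", "gb_polar", "nonpolar", "total"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing energy columns {sorted(missing)}")
    return df
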