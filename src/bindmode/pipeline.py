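"""End-to-end pipeline: energies → segmentation → alanine scan → interactions
→ hotspot report.

A declarative YAML/dict config describes two systems — the natural-ligand
(``atp``) complex and the inhibitor complex — either as generated toy
complexes or as structure/trajectory files. Each stage writes a CSV artifact
with a metadata header (config hash, seed, parameters); a fixed seed makes
the whole run byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alascan import alanine_scan, contributions_to_frame
from .energetics import EnergyParams, select_key_waters, trajectory_energies
from .hotspots import (
    benchmark_overlap,
    differential_hotspots,
    hotspot_frame,
    mark_literature,
    normalize_profile,
    profile_from_scan,
)
from .interactions import coordination_numbers, detect_hbonds
from .io import config_hash, read_structure, read_trajectory, write_structure, write_table
from .model import BindingModeModel
from .simulate import ToyComplexSpec, gen_toy_complex
from .structures import BindingPartition


class ConfigError(ValueError):
    """Raised for invalid pipeline configurations (before any computation)."""


DEFAULTS = {
    "seed": 0,
    "segmentation": {"penalty": "auto", "min_len": 20, "merge_gap": 2.0},
    "scan": {"stride_ps": 10.0, "keep_key_waters": True},
    "energy": {"sasa_points": 128, "gamma": 0.0072, "beta": 0.0, "probe_radius": 1.4},
    "hotspots": {"tau_inhibitor": 0.25, "tau_atp": 0.10, "literature": None},
}


def load_config(source) -> dict:
    """Read and validate a pipeline config (YAML path or dict)."""
    import yaml

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    for key, default in DEFAULTS.items():
        if isinstance(default, dict):
            cfg[key] = {**default, **cfg.get(key, {})}
        else:
            cfg.setdefault(key, default)
    if "outdir" not in cfg:
        raise ConfigError("config must set 'outdir'")
    systems = cfg.get("systems")
    if not systems or set(systems) != {"atp", "inhibitor"}:
        raise ConfigError("config must define exactly the systems 'atp' and 'inhibitor'")
    for name, sys_cfg in systems.items():
        if "toy" in sys_cfg:
            continue
        for field in ("structure", "trajectory"):
            p = sys_cfg.get(field)
            if not p:
                raise ConfigError(f"system {name!r}: missing {field} path")
            if not Path(p).exists():
                raise ConfigError(f"system {name!r}: {field} path {p} does not exist")
    return cfg


def _load_system(name: str, sys_cfg: dict, seed: int):
    """Returns (structure, [trajectories])."""
    if "toy" in sys_cfg:
        spec = ToyComplexSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in (sys_cfg["toy"] or {}).items()})
        n_rep = int(sys_cfg.get("n_replicates", 1))
        trajs = []
        structure = None
        for rep in range(n_rep):
            s, t = gen_toy_complex(spec, seed=seed + rep)
            structure = structure or s
            trajs.append(t)
        return structure, trajs
    structure = read_structure(sys_cfg["structure"])
    return structure, [read_trajectory(sys_cfg["trajectory"], structure)]


def run_pipeline(config, verbose: bool = True) -> Path:
    """Run every stage; returns the output directory.

    Writes per system: structure, energies, macrostate table, assignment,
    alanine-scan profile of the tightest macrostate, interaction tables; then
    the combined hotspot report. Any stage failure aborts with the stage name
    while keeping upstream outputs on disk.
    """
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    hashed = {k: v for k, v in cfg.items() if k != "outdir"}
    meta_base = {"bindmode_version": __version__, "seed": seed, "config_hash": config_hash(hashed)}
    log_lines = [f"bindmode {__version__} pipeline", f"config_hash: {meta_base['config_hash']}"]

    def log(msg):
        log_lines.append(msg)
        if verbose:
            print(msg)

    params = EnergyParams(
        gamma=cfg["energy"]["gamma"],
        beta=cfg["energy"]["beta"],
        probe_radius=cfg["energy"]["probe_radius"],
        sasa_points=int(cfg["energy"]["sasa_points"]),
    )

    profiles = {}
    stage = "setup"
    try:
        for name in ("atp", "inhibitor"):
            sys_cfg = cfg["systems"][name]
            stage = f"{name}:load"
            structure, trajs = _load_system(name, sys_cfg, seed)
            write_structure(structure, outdir / f"{name}_structure.pqr")

            stage = f"{name}:key_waters"
            key_waters = select_key_waters(trajs[0])
            partition = BindingPartition(ligand_water_residues=frozenset(key_waters))
            log(f"[{name}] key waters: {key_waters}")

            stage = f"{name}:energies"
            energies = pd.concat(
                [trajectory_energies(t, partition, params, replicate=r)
                 for r, t in enumerate(trajs)],
                ignore_index=True,
            )
            write_table(energies, outdir / f"{name}_energies.csv", meta_base)

            stage = f"{name}:segmentation"
            model = BindingModeModel(
                energies,
                penalty=cfg["segmentation"]["penalty"],
                min_len=int(cfg["segmentation"]["min_len"]),
                merge_gap=float(cfg["segmentation"]["merge_gap"]),
            )
            res = model.fit()
            write_table(res.table, outdir / f"{name}_macrostates.csv", meta_base)
            write_table(res.assignment, outdir / f"{name}_assignment.csv", meta_base)
            log(f"[{name}] macrostates: {res.n_states} "
                f"(dominant {res.dominant_state()} {res.occupancies.max():.1f}%)")

            stage = f"{name}:alanine_scan"
            tight = res.tightest_state()
            frames = res.frames_of(tight)
            interval = trajs[0].frame_interval_ps
            stride = max(1, round(float(cfg["scan"]["stride_ps"]) / interval))
            contribs = _pooled_scan(
                trajs, frames, partition, params, stride,
                tight, bool(cfg["scan"]["keep_key_waters"]),
            )
            write_table(contributions_to_frame(contribs),
                        outdir / f"{name}_alascan_{tight}.csv", meta_base)
            profiles[name] = normalize_profile(profile_from_scan(contribs))

            stage = f"{name}:interactions"
            idir = outdir / "interactions"
            idir.mkdir(exist_ok=True)
            hb = detect_hbonds(structure)
            write_table(
                pd.DataFrame(
                    [{"donor": h.donor_atom_id, "acceptor": h.acceptor_atom_id,
                      "distance": h.distance, "angle": h.angle} for h in hb]
                ),
                idir / f"{name}_hbonds.csv",
                meta_base,
            )
            ions = [a.atom_id for a in structure.atoms if a.entity == "ion"]
            coord_rows = []
            for ion in ions:
                cn = coordination_numbers(trajs[0], ion)
                coord_rows.append(
                    {"ion_atom_id": ion, "mean_coordination": float(cn.mean()),
                     "frac_hexacoordinated": float(np.mean(cn == 6))}
                )
            write_table(pd.DataFrame(coord_rows), idir / f"{name}_coordination.csv", meta_base)

        stage = "hotspots"
        hcfg = cfg["hotspots"]
        records = differential_hotspots(
            profiles["atp"], profiles["inhibitor"],
            tau_inhibitor=float(hcfg["tau_inhibitor"]), tau_atp=float(hcfg["tau_atp"]),
        )
        summary = {
            "tau_inhibitor": hcfg["tau_inhibitor"],
            "tau_atp": hcfg["tau_atp"],
            "candidates": sorted(h.residue_index for h in records if h.candidate),
        }
        if hcfg.get("literature"):
            lit = [int(l.split()[-1]) for l in Path(hcfg["literature"]).read_text().splitlines()
                   if l.strip() and not l.startswith("#")]
            records = mark_literature(records, lit)
            summary["benchmark"] = benchmark_overlap(
                summary["candidates"], lit, [h.residue_index for h in records]
            )
        write_table(hotspot_frame(records), outdir / "hotspots.csv", meta_base)
        (outdir / "hotspots_summary.json").write_text(json.dumps(summary, indent=2))
        log(f"[hotspots] candidates: {summary['candidates']}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def _pooled_scan(trajs, frames: pd.DataFrame, partition, params, stride, label, keep_kw):
    """Alanine scan pooled over replicates (snapshot-weighted means/SDs)."""
    per_rep = []
    for rep, grp in frames.groupby("replicate"):
        idx = grp["frame"].astype(int).tolist()
        if not idx:
            continue
        per_rep.append(
            alanine_scan(trajs[int(rep)], idx, partition, params, stride=stride,
                         macrostate_label=label, keep_key_waters=keep_kw)
        )
    if not per_rep:
        raise RuntimeError("no snapshots available for the alanine scan")
    if len(per_rep) == 1:
        return per_rep[0]
    pooled = []
    for contribs in zip(*per_rep):
        n = sum(c.n_snapshots for c in contribs)
        mean = sum(c.ddg_mean * c.n_snapshots for c in contribs) / n
        var = sum(c.n_snapshots * (c.ddg_sd**2 + (c.ddg_mean - mean) ** 2) for c in contribs) / n
        c0 = contribs[0]
        pooled.append(
            type(c0)(c0.residue_index, c0.residue_name, label,
                     float(mean), float(np.sqrt(var)), int(n), c0.mutated)
        )
    return pooled
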