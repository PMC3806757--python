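"""Differential hotspot scoring: inhibitor-critical vs substrate-critical residues.

Residue contribution profiles from the natural-ligand (ATP) system and the
inhibitor system are normalized to [0, 1] and contrasted. A residue is a
putative resistance hotspot when it contributes substantially to inhibitor
binding but only marginally to ATP binding — its mutation can abolish drug
binding while sparing catalysis. Residues critical for ATP binding are under
purifying selection and are excluded regardless of their inhibitor
contribution.

Profiles here are per-residue *binding-energy contributions* (kcal/mol,
negative = favourable, i.e. −ΔΔG from the alanine scan); normalization maps
the strongest favourable contributor to 1 and floors unfavourable values at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import hypergeom

DEFAULT_TAU_INHIBITOR = 0.25
DEFAULT_TAU_ATP = 0.10


class HotspotError(ValueError):
    """Raised for inconsistent hotspot inputs."""


@dataclass(frozen=True)
class HotspotRecord:
    residue_index: int
    norm_atp: float
    norm_inhibitor: float
    differential: float
    candidate: bool
    literature_hit: bool = False

    def __post_init__(self):
        if abs(self.differential - (self.norm_inhibitor - self.norm_atp)) > 1e-9:
            raise HotspotError("differential must equal norm_inhibitor − norm_atp")


def profile_from_scan(contribs) -> dict[int, float]:
    """Alanine-scan output → per-residue binding-energy contribution (−ΔΔG)."""
    return {c.residue_index: -c.ddg_mean for c in contribs}


def normalize_profile(profile) -> dict[int, float]:
    """Scale favourable contributions into [0, 1].

    ``value = max(0, −x) / max_residues max(0, −x)``: the strongest favourable
    (most negative) contributor maps to exactly 1; unfavourable contributions
    floor at 0. An all-zero (or all-unfavourable) profile maps to all zeros.
    Accepts a mapping residue→contribution or an alanine-scan contribution list.
    """
    if not isinstance(profile, Mapping):
        profile = profile_from_scan(profile)
    fav = {r: max(0.0, -float(v)) for r, v in profile.items()}
    top = max(fav.values(), default=0.0)
    if top == 0.0:
        return {r: 0.0 for r in fav}
    return {r: v / top for r, v in fav.items()}


def differential_hotspots(
    atp_profile: Mapping[int, float],
    inhibitor_profile: Mapping[int, float],
    tau_inhibitor: float = DEFAULT_TAU_INHIBITOR,
    tau_atp: float = DEFAULT_TAU_ATP,
) -> list[HotspotRecord]:
    """Contrast two *normalized* profiles over the same residue set.

    Candidates satisfy norm_inhibitor ≥ τ_inh and norm_atp ≤ τ_atp. Records
    are sorted by differential descending, ties broken by residue index.
    """
    if set(atp_profile) != set(inhibitor_profile):
        raise HotspotError("profiles must cover the same residue set")
    records = []
    for r in atp_profile:
        na, ni = float(atp_profile[r]), float(inhibitor_profile[r])
        records.append(
            HotspotRecord(
                residue_index=int(r),
                norm_atp=na,
                norm_inhibitor=ni,
                differential=ni - na,
                candidate=(ni >= tau_inhibitor and na <= tau_atp),
            )
        )
    records.sort(key=lambda h: (-h.differential, h.residue_index))
    return records


def mark_literature(records: list, positions: Iterable[int]) -> list:
    """Flag records whose residue index appears in a literature mutation list."""
    positions = set(int(p) for p in positions)
    return [replace(h, literature_hit=h.residue_index in positions) for h in records]


def benchmark_overlap(candidates, literature_positions, universe) -> dict:
    """Overlap between predicted candidates and a literature mutation list.

    ``universe`` is either the full residue index collection or its size.
    Returns counts plus the hypergeometric tail probability
    P(overlap ≥ observed) for drawing ``len(candidates)`` residues at random
    from the universe when ``len(literature)`` of them are marked.
    """
    cand = set(int(c) for c in candidates)
    lit = set(int(p) for p in literature_positions)
    if isinstance(universe, (int, np.integer)):
        m = int(universe)
        if len(lit) > m or len(cand) > m:
            raise HotspotError("more positions than the universe size")
    else:
        uni = set(int(u) for u in universe)
        m = len(uni)
        outside = lit - uni
        if outside:
            raise HotspotError(f"literature positions outside the universe: {sorted(outside)}")
        bad = cand - uni
        if bad:
            raise HotspotError(f"candidate positions outside the universe: {sorted(bad)}")
    k = len(cand & lit)
    # P(X >= k), X ~ Hypergeom(M=m, K=len(lit), n=len(cand))
    p = float(hypergeom.sf(k - 1, m, len(lit), len(cand))) if cand else 1.0
    return {
        "n_candidates": len(cand),
        "n_literature": len(lit),
        "n_overlap": k,
        "universe_size": m,
        "p_value": min(p, 1.0),
    }


def hotspot_frame(records: list):
    """Tabular (pandas) view of hotspot records."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "residue_index": h.residue_index,
                "norm_atp": h.norm_atp,
                "norm_inhibitor": h.norm_inhibitor,
                "differential": h.differential,
                "candidate": h.candidate,
                "literature_hit": h.literature_hit,
            }
            for h in records
        ]
    )
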