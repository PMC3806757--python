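"""Published per-macrostate MM-GBSA statistics for the four ErbB-family systems.

The bundled table lists, for each system (EGFR / ErbB2, active with ATP or
inactive with lapatinib) and each binding-mode subpopulation, the occupancy and
the mean ± SD of the four energy components and of the total binding energy
(kcal/mol). Two rows whose printed component means do not sum to the printed
total within rounding are flagged ``consistent=False``.

These statistics are the study conditions the synthetic generator emulates.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

SYSTEMS = ("EGFRa-ATP", "ErbB2a-ATP", "EGFRi-FMM", "ErbB2i-FMM")
COMPONENTS = ("vdw", "ele", "gb_polar", "nonpolar")


def macrostate_table() -> pd.DataFrame:
    """The bundled reference table as a DataFrame (one row per subpopulation)."""
    ref = importlib.resources.files("bindmode.data") / "reference_macrostates.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["consistent"] = df["consistent"].astype(bool)
    return df


def system_states(system: str) -> pd.DataFrame:
    """Rows of :func:`macrostate_table` for one system."""
    df = macrostate_table()
    if system not in SYSTEMS:
        raise KeyError(f"unknown system {system!r}; choose from {SYSTEMS}")
    return df[df["system"] == system].reset_index(drop=True)


def literature_positions(kinase: str) -> list[int]:
    """Residue indices reported as lapatinib-resistance sites for one kinase."""
    ref = importlib.resources.files("bindmode.data") / "literature_mutations.txt"
    out = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, pos = line.split()
        if name == kinase:
            out.append(int(pos))
    if not out:
        raise KeyError(f"no literature positions recorded for kinase {kinase!r}")
    return sorted(out)
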