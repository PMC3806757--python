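"""Model/Results interface for binding-mode decomposition.

``BindingModeModel`` wraps an energy-component table (replicate, frame, four
components, total) and ``fit()`` performs change-point segmentation of each
replicate's total-energy series followed by macrostate clustering. The
returned ``BindingModeResults`` carries the macrostates, per-frame
assignment, occupancies and a printable summary in the layout of the
published per-subpopulation table.

    >>> model = BindingModeModel(energies)        # doctest: +SKIP
    >>> res = model.fit()                         # doctest: +SKIP
    >>> print(res.summary())                      # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import segmentation as seg
from .io import read_energy_csv


class BindingModeModel:
    """Penalized change-point model for macrostate discovery.

    Parameters
    ----------
    energies : DataFrame with columns replicate, frame, vdw, ele, gb_polar,
        nonpolar, total (kcal/mol; frames 0-based and contiguous per replicate).
    penalty : per-change-point penalty for the Gaussian mean-shift cost, or
        "auto" for σ̂²·log n with σ̂ from the MAD of first differences.
    min_len : minimum segment length in frames.
    merge_gap : minimum separation (kcal/mol) between macrostate means.
    refine : sharpen the frame assignment by penalized step-fitting after
        clustering (recommended; see segmentation module docs).
    """

    def __init__(
        self,
        energies: pd.DataFrame,
        penalty="auto",
        min_len: int = seg.DEFAULT_MIN_LEN,
        merge_gap: float = seg.DEFAULT_MERGE_GAP,
        refine: bool = True,
    ):
        required = {"replicate", "frame", "total"}
        if not required <= set(energies.columns):
            raise ValueError(f"energies table must carry columns {sorted(required)}")
        self.energies = energies.sort_values(["replicate", "frame"]).reset_index(drop=True)
        self.penalty = penalty
        self.min_len = min_len
        self.merge_gap = merge_gap
        self.refine = refine

    @classmethod
    def from_csv(cls, path, **kw) -> "BindingModeModel":
        return cls(read_energy_csv(path), **kw)

    @classmethod
    def simulate(cls, config, **kw):
        """Generate a synthetic series from a GeneratorConfig and wrap it.

        Returns (model, ground_truth)."""
        from .simulate import gen_energy_series

        df, truth = gen_energy_series(config)
        return cls(df, **kw), truth

    def fit(self) -> "BindingModeResults":
        segments = seg.segment_energies(self.energies, penalty=self.penalty, min_len=self.min_len)
        macrostates = seg.build_macrostates(
            segments, self.energies, merge_gap=self.merge_gap, refine=self.refine
        )
        return BindingModeResults(self, segments, macrostates)


class BindingModeResults:
    """Fitted macrostate decomposition."""

    def __init__(self, model: BindingModeModel, segments, macrostates):
        self.model = model
        self.segments = segments
        self.macrostates = macrostates
        self.table = seg.macrostate_table(macrostates)
        self.assignment = seg.assignment_frame(macrostates)

    @property
    def n_states(self) -> int:
        return len(self.macrostates)

    @property
    def occupancies(self) -> pd.Series:
        return self.table.set_index("state")["occupancy_pct"]

    @property
    def state_means(self) -> pd.Series:
        return self.table.set_index("state")["total_mean"]

    def dominant_state(self) -> str:
        return str(self.table.loc[self.table["occupancy_pct"].idxmax(), "state"])

    def tightest_state(self) -> str:
        return str(self.table.loc[self.table["total_mean"].idxmin(), "state"])

    def frames_of(self, state: str) -> pd.DataFrame:
        """(replicate, frame) rows assigned to one macrostate."""
        return self.assignment[self.assignment["state"] == state][["replicate", "frame"]]

    def summary(self) -> str:
        lines = [
            "Binding-mode decomposition",
            "==========================",
            f"replicates: {self.energies_n_replicates()}   "
            f"frames/replicate: {self.energies_n_frames()}   "
            f"macrostates: {self.n_states}",
            "",
            "state  %occ      vdw            ele          gb_polar       nonpolar        total",
        ]
        for _, r in self.table.iterrows():
            cells = [f"{r['state']:<5s}", f"{r['occupancy_pct']:5.1f}"]
            for c in ("vdw", "ele", "gb_polar", "nonpolar", "total"):
                cells.append(f"{r[f'{c}_mean']:8.1f}±{r[f'{c}_sd']:<4.1f}")
            lines.append("  ".join(cells))
        return "\n".join(lines)

    def energies_n_replicates(self) -> int:
        return self.model.energies["replicate"].nunique()

    def energies_n_frames(self) -> int:
        return int(self.model.energies.groupby("replicate")["frame"].count().iloc[0])

    def plot(self, ax=None):
        """Total-energy series coloured by macrostate (matplotlib)."""
        import matplotlib.pyplot as plt

        merged = self.model.energies.merge(self.assignment, on=["replicate", "frame"])
        reps = sorted(merged["replicate"].unique())
        if ax is None:
            _, axes = plt.subplots(len(reps), 1, sharex=True, squeeze=False)
            axes = axes[:, 0]
        else:
            axes = np.atleast_1d(ax)
        for a, rep in zip(axes, reps):
            grp = merged[merged["replicate"] == rep]
            for state, sub in grp.groupby("state"):
                a.plot(sub["frame"], sub["total"], ".", ms=1, label=state)
            a.set_ylabel(f"rep {rep}")
        axes[-1].set_xlabel("frame")
        axes[0].legend(markerscale=10, fontsize="small")
        return axes
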