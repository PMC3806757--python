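"""Change-point segmentation of binding-energy series and macrostate building.

The total binding-energy series of each replicate is split into contiguous
segments by exact penalized optimal partitioning under a Gaussian mean-shift
cost (sum of squared deviations from the segment mean). Segments from all
replicates are then pooled and clustered into macrostates — subpopulations of
the binding-energy landscape — and per-macrostate component statistics are
reported in the layout of the reference table (occupancy %, mean ± SD per
component and for the total).

Clustering uses a length-weighted kernel density over segment means with a
per-segment bandwidth equal to the sampling noise of that mean (c·σ̂/√L);
macrostates are cut at density valleys and modes closer than ``merge_gap``
are merged. This resolves modes separated by little more than the
segment-mean noise, which nearest-neighbour (single-linkage) merging cannot:
with overlapping segment-mean clouds single linkage chains across any gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPONENTS = ("vdw", "ele", "gb_polar", "nonpolar")

DEFAULT_MIN_LEN = 20
DEFAULT_MERGE_GAP = 2.0
#: penalty = PENALTY_FACTOR · σ̂² · log n; chosen for sensitivity to mode
#: separations of ~Δ at dwell scales of tens of frames (see docs/methods.md)
PENALTY_FACTOR = 1.0
#: bandwidth multiplier on the segment-mean sampling noise σ̂/√L
KDE_BANDWIDTH_FACTOR = 1.2


class SegmentationError(ValueError):
    """Raised for invalid segmentation inputs."""


@dataclass(frozen=True)
class Segment:
    """Contiguous run of frames [start, end) within one replicate."""

    replicate: int
    start: int
    end: int
    mean: float
    variance: float

    def __post_init__(self):
        if self.end <= self.start:
            raise SegmentationError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Macrostate:
    """A labelled subpopulation: member segments plus pooled statistics."""

    label: str
    segments: list
    occupancy_pct: float
    component_stats: dict      # component -> (mean, sd)
    total_stat: tuple          # (mean, sd)
    n_frames: int


def estimate_noise_sd(y: np.ndarray) -> float:
    """Robust within-state noise SD via the MAD of first differences.

    First differences are insensitive to slow mean shifts; the scaling
    0.6745·√2 maps the median absolute difference of iid Gaussians to σ.
    """
    y = np.asarray(y, float)
    if len(y) < 3:
        raise SegmentationError("need at least 3 points to estimate noise")
    mad = np.median(np.abs(np.diff(y)))
    return float(mad / (0.6745 * np.sqrt(2.0))) if mad > 0 else 0.0


def default_penalty(y: np.ndarray) -> float:
    """Automatic per-change-point penalty: PENALTY_FACTOR · σ̂² · log n."""
    return PENALTY_FACTOR * estimate_noise_sd(y) ** 2 * np.log(len(y))


def segment_series(
    y: np.ndarray,
    penalty: float | str = "auto",
    min_len: int = DEFAULT_MIN_LEN,
    replicate: int = 0,
) -> list[Segment]:
    """Exact minimizer of  Σ_segments SSE(segment) + penalty·(#segments − 1).

    Dynamic programming over all admissible last-change positions; O(n²) but
    fully vectorized, deterministic, and provably optimal for the stated cost.
    """
    y = np.asarray(y, float)
    n = len(y)
    if not np.all(np.isfinite(y)):
        raise SegmentationError("series contains non-finite values")
    if min_len < 1:
        raise SegmentationError("min_len must be >= 1")
    if n < 2 * min_len:
        raise SegmentationError(f"series length {n} is below 2*min_len = {2 * min_len}")
    if penalty == "auto":
        penalty = default_penalty(y)
    penalty = float(penalty)
    if penalty < 0:
        raise SegmentationError("penalty must be non-negative")

    cs = np.concatenate([[0.0], np.cumsum(y)])
    css = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost_vec(starts: np.ndarray, end: int) -> np.ndarray:
        ln = end - starts
        s = cs[end] - cs[starts]
        return (css[end] - css[starts]) - s * s / ln

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for t in range(min_len, n + 1):
        starts = np.arange(0, t - min_len + 1)
        cand = F[starts] + seg_cost_vec(starts, t) + penalty
        j = int(np.argmin(cand))
        F[t] = cand[j]
        prev[t] = starts[j]

    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(prev[bounds[-1]]))
    bounds = bounds[::-1]

    segments = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        seg = y[s:e]
        segments.append(
            Segment(replicate=replicate, start=s, end=e,
                    mean=float(seg.mean()), variance=float(seg.var()))
        )
    return segments


def segment_energies(
    energies: pd.DataFrame,
    penalty: float | str = "auto",
    min_len: int = DEFAULT_MIN_LEN,
) -> list[Segment]:
    """Segment the total-energy series of every replicate in an energy table."""
    segments = []
    for rep, grp in energies.groupby("replicate"):
        y = grp.sort_values("frame")["total"].to_numpy()
        segments.extend(segment_series(y, penalty=penalty, min_len=min_len, replicate=int(rep)))
    return segments


def segmentation_cost(y: np.ndarray, segments: list, penalty: float) -> float:
    """Penalized cost of a segmentation (for optimality cross-checks)."""
    y = np.asarray(y, float)
    cost = penalty * (len(segments) - 1)
    for s in segments:
        seg = y[s.start:s.end]
        cost += float(np.sum((seg - seg.mean()) ** 2))
    return cost


# --------------------------------------------------------------------------
# Macrostates
# --------------------------------------------------------------------------

def _cluster_segment_means(
    means: np.ndarray, lengths: np.ndarray, noise_sds: np.ndarray, merge_gap: float
) -> np.ndarray:
    """Cluster 1-D segment means; returns integer labels per segment.

    Length-weighted Gaussian KDE with per-segment bandwidth
    KDE_BANDWIDTH_FACTOR · σ̂/√L (never below a small floor); clusters are the
    basins between density minima, then modes whose pooled means are closer
    than ``merge_gap`` are merged, nearest pair first.
    """
    h = KDE_BANDWIDTH_FACTOR * noise_sds / np.sqrt(lengths)
    floor = max(1e-6, 1e-3 * (means.max() - means.min()))
    h = np.maximum(h, floor)
    lo, hi = (means - 4 * h).min(), (means + 4 * h).max()
    grid = np.linspace(lo, hi, 2048)
    dens = np.zeros_like(grid)
    for m, L, hh in zip(means, lengths, h):
        dens += L * np.exp(-0.5 * ((grid - m) / hh) ** 2) / hh
    # valley positions: local minima strictly between local maxima
    interior = (dens[1:-1] <= dens[:-2]) & (dens[1:-1] <= dens[2:])
    valleys = grid[1:-1][interior]
    # collapse plateaus of equal density
    cuts = []
    for v in valleys:
        if not cuts or v - cuts[-1] > (hi - lo) / 1000:
            cuts.append(v)
    labels = np.searchsorted(np.asarray(cuts), means)

    # merge modes closer than merge_gap (weighted means, nearest pair first)
    def pooled_means(lbl):
        uniq = np.unique(lbl)
        pm = np.array([np.average(means[lbl == u], weights=lengths[lbl == u]) for u in uniq])
        return uniq, pm

    while True:
        uniq, pm = pooled_means(labels)
        if len(uniq) < 2:
            break
        order = np.argsort(pm)
        gaps = np.diff(pm[order])
        k = int(np.argmin(gaps))
        if gaps[k] >= merge_gap:
            break
        a, b = uniq[order[k]], uniq[order[k + 1]]
        labels[labels == b] = a
    # renumber consecutively
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _potts_labels(dev: np.ndarray, switch_penalty: float) -> np.ndarray:
    """Exact minimizer of Σ_t dev[t, lab_t] + switch_penalty · #label changes.

    Dynamic program over label paths (1-D Potts model with fixed levels);
    O(n·K) using the single-best-predecessor trick.
    """
    n, K = dev.shape
    D = dev[0].copy()
    back = np.zeros((n, K), np.int16)
    idx = np.arange(K)
    for t in range(1, n):
        best_j = int(np.argmin(D))
        switch = D[best_j] + switch_penalty
        stay = D <= switch
        back[t] = np.where(stay, idx, best_j)
        D = np.where(stay, D, switch) + dev[t]
    lab = np.empty(n, int)
    lab[-1] = int(np.argmin(D))
    for t in range(n - 1, 0, -1):
        lab[t - 1] = back[t, lab[t]]
    return lab


def _refine_assignment(
    series: dict,
    levels: np.ndarray,
    sds: np.ndarray,
    init_dwell: float,
    n_iter: int = 10,
) -> dict:
    """Sharpen frame→state assignment by heteroscedastic penalized step-fitting.

    Alternates (i) an exact Potts label fit per replicate under the Gaussian
    deviance (y−μ_k)²/σ_k² + 2·ln σ_k with a dwell-matched switch penalty
    2·ln(dwell−1), and (ii) re-estimation of the level means μ_k from the
    assigned frames. The per-state SDs stay fixed at their initial estimates
    (re-estimating them lets a contaminated wide state absorb its neighbours).
    Recovers short excursions that the min-length-constrained segmentation
    cannot resolve and places boundaries at likelihood crossings.
    """
    levels = levels.copy()
    sds = np.maximum(sds.copy(), 1e-12)
    ys = {r: grp["total"].to_numpy() for r, grp in series.items()}
    total_frames = sum(len(y) for y in ys.values())
    labels = {}
    dwell = max(init_dwell, 3.0)
    prev_labels = None
    for _ in range(n_iter):
        pen = 2.0 * np.log(max(dwell - 1.0, 2.0))
        for r, y in ys.items():
            dev = (y[:, None] - levels[None, :]) ** 2 / sds[None, :] ** 2 + 2.0 * np.log(
                sds[None, :]
            )
            labels[r] = _potts_labels(dev, pen)
        n_runs = sum(1 + int(np.sum(np.diff(l) != 0)) for l in labels.values())
        dwell = total_frames / n_runs
        for k in range(len(levels)):
            vals = np.concatenate([y[labels[r] == k] for r, y in ys.items()])
            if len(vals) >= 10:
                levels[k] = vals.mean()
        if prev_labels is not None and all(
            np.array_equal(labels[r], prev_labels[r]) for r in labels
        ):
            break
        prev_labels = {r: l.copy() for r, l in labels.items()}
    return labels


def _segments_from_labels(labels: dict, series: dict) -> tuple[list, np.ndarray]:
    """Contiguous label runs → Segment objects; returns (segments, run_labels)."""
    segments, run_labels = [], []
    for r, lab in labels.items():
        y = series[r]["total"].to_numpy()
        bounds = np.concatenate([[0], np.nonzero(np.diff(lab) != 0)[0] + 1, [len(lab)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            seg = y[s:e]
            segments.append(
                Segment(replicate=r, start=int(s), end=int(e),
                        mean=float(seg.mean()), variance=float(seg.var()))
            )
            run_labels.append(lab[s])
    return segments, np.array(run_labels, int)


def build_macrostates(
    segments: list,
    energies: pd.DataFrame,
    merge_gap: float = DEFAULT_MERGE_GAP,
    refine: bool = True,
) -> list[Macrostate]:
    """Pool segments across replicates into macrostates with Table-style stats.

    Segment means are clustered into modes (density-valley cut + merge_gap);
    with ``refine=True`` (default) the frame→state assignment is then
    sharpened by :func:`_refine_assignment` while keeping the discovered mode
    structure. Macrostates are ordered by total-energy mean ascending
    (tightest binding first) and labelled ``S1, S2, …`` by that rank.
    """
    if merge_gap <= 0:
        raise SegmentationError("merge_gap must be positive")
    if not segments:
        raise SegmentationError("no segments supplied")

    reps = sorted(energies["replicate"].unique())
    series = {
        int(r): energies[energies["replicate"] == r].sort_values("frame")
        for r in reps
    }
    covered = {r: np.zeros(len(series[r]), bool) for r in series}
    for s in segments:
        if s.replicate not in covered:
            raise SegmentationError(f"segment references unknown replicate {s.replicate}")
        covered[s.replicate][s.start:s.end] = True
    for r, mask in covered.items():
        if not mask.all():
            raise SegmentationError(f"segments do not cover all frames of replicate {r}")

    means = np.array([s.mean for s in segments])
    lengths = np.array([s.length for s in segments], float)
    noise = {r: estimate_noise_sd(series[r]["total"].to_numpy()) for r in series}
    noise_sds = np.array([noise[s.replicate] for s in segments])

    if len(segments) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        labels = _cluster_segment_means(means, lengths, noise_sds, merge_gap)

    def pooled_frames(members):
        return pd.concat(
            [series[s.replicate].iloc[s.start:s.end] for s in members], ignore_index=True
        )

    n_modes = len(np.unique(labels))
    if refine and n_modes > 1:
        levels, sds = np.empty(n_modes), np.empty(n_modes)
        for k in range(n_modes):
            fr = pooled_frames([s for s, l in zip(segments, labels) if l == k])
            levels[k] = fr["total"].mean()
            sds[k] = max(fr["total"].std(ddof=0), 1e-12)
        frame_labels = _refine_assignment(
            series, levels, sds, init_dwell=float(np.mean(lengths))
        )
        segments, labels = _segments_from_labels(frame_labels, series)

    total_frames = sum(len(g) for g in series.values())
    states = []
    for lbl in np.unique(labels):
        members = [s for s, l in zip(segments, labels) if l == lbl]
        frames = pooled_frames(members)
        comp_stats = {
            c: (float(frames[c].mean()), float(frames[c].std(ddof=0))) for c in COMPONENTS
        }
        states.append(
            Macrostate(
                label="",
                segments=members,
                occupancy_pct=100.0 * len(frames) / total_frames,
                component_stats=comp_stats,
                total_stat=(float(frames["total"].mean()), float(frames["total"].std(ddof=0))),
                n_frames=len(frames),
            )
        )
    states.sort(key=lambda m: m.total_stat[0])
    for rank, m in enumerate(states, start=1):
        m.label = f"S{rank}"
    return states


def macrostate_table(macrostates: list) -> pd.DataFrame:
    """One row per macrostate: occupancy and mean ± SD per component and total."""
    rows = []
    for m in macrostates:
        row = {"state": m.label, "occupancy_pct": m.occupancy_pct, "n_frames": m.n_frames}
        for c in COMPONENTS:
            row[f"{c}_mean"], row[f"{c}_sd"] = m.component_stats[c]
        row["total_mean"], row["total_sd"] = m.total_stat
        rows.append(row)
    df = pd.DataFrame(rows)
    if abs(df["occupancy_pct"].sum() - 100.0) > 0.5:
        raise SegmentationError("macrostate occupancies do not sum to 100")
    return df


def assignment_frame(macrostates: list) -> pd.DataFrame:
    """Per-frame state assignment (replicate, frame, state)."""
    rows = []
    for m in macrostates:
        for s in m.segments:
            rows.append(
                pd.DataFrame(
                    {"replicate": s.replicate, "frame": np.arange(s.start, s.end), "state": m.label}
                )
            )
    return (
        pd.concat(rows, ignore_index=True)
        .sort_values(["replicate", "frame"])
        .reset_index(drop=True)
    )
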