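"""Peak-centered signal aggregation.

Turns sparse genome-wide tracks into peaks x offset-bins matrices
(heatmap rows), metagene averages, per-locus-normalized nucleosome
profiles, and between-class enrichment comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    FragmentSet,
    Parameters,
    PeakSet,
    SignalTrack,
    ValidationError,
    coverage_track,
    midpoint_track,
)

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Peaks x offset-bins matrix of signal density around peak midpoints."""

    peak_ids: list
    offsets: np.ndarray  # bin-center offsets relative to the peak midpoint
    values: np.ndarray  # shape (n_peaks, n_bins), density per bp
    bin_bp: int
    window_bp: int

    def __post_init__(self):
        if self.values.shape != (len(self.peak_ids), len(self.offsets)):
            raise ValidationError("ProfileMatrix shape mismatch")

    def row(self, peak_id) -> np.ndarray:
        return self.values[self.peak_ids.index(peak_id)]


@dataclass
class MetageneProfile:
    """Average density as a function of offset from the anchor midpoint."""

    offsets: np.ndarray
    mean_density: np.ndarray
    n_peaks: int

    def __post_init__(self):
        if len(self.offsets) != len(self.mean_density):
            raise ValidationError("MetageneProfile length mismatch")


def bin_offsets(window_bp: int, bin_bp: int) -> np.ndarray:
    """Bin-center offsets for bins tiling [-window/2, +window/2)."""
    if window_bp % bin_bp:
        raise ValidationError("window_bp must be divisible by bin_bp")
    edges = np.arange(-window_bp // 2, window_bp // 2 + 1, bin_bp)
    return (edges[:-1] + edges[1:]) / 2.0


def profile_matrix(
    track: SignalTrack, peaks: PeakSet, window_bp: int, bin_bp: int
) -> ProfileMatrix:
    """One binned density row per peak; windows overhanging a chromosome
    end are zero-padded."""
    offsets = bin_offsets(window_bp, bin_bp)
    values = np.zeros((len(peaks), len(offsets)))
    for i, row in enumerate(peaks.df.itertuples(index=False)):
        values[i] = track.window_profile(row.chrom, row.midpoint, window_bp, bin_bp)
    return ProfileMatrix(list(peaks.ids), offsets, values, bin_bp, window_bp)


def metagene(matrix: ProfileMatrix, subset=None) -> MetageneProfile:
    """Column means over a subset of rows (all rows when subset is None)."""
    if subset is None:
        idx = np.arange(len(matrix.peak_ids))
    else:
        wanted = list(subset)
        if not wanted:
            raise ValidationError("metagene subset is empty")
        lookup = {pid: i for i, pid in enumerate(matrix.peak_ids)}
        idx = np.array([lookup[pid] for pid in wanted])
    if idx.size == 0:
        raise ValidationError("metagene subset is empty")
    return MetageneProfile(matrix.offsets, matrix.values[idx].mean(axis=0), len(idx))


def moving_average(v, n: int) -> np.ndarray:
    """Centered moving average over n bins; edges use truncated windows."""
    if n % 2 == 0:
        raise ValidationError("moving-average window must be odd")
    v = np.asarray(v, dtype=float)
    if n > len(v):
        raise ValidationError("moving-average window longer than vector")
    kernel = np.ones(n)
    sums = np.convolve(v, kernel, mode="same")
    counts = np.convolve(np.ones(len(v)), kernel, mode="same")
    return sums / counts


def mnase_metagene(
    fragments: FragmentSet,
    peaks: PeakSet,
    params: Parameters | None = None,
    mode: str = "coverage",
    genome: dict | None = None,
    track: SignalTrack | None = None,
):
    """Per-locus-normalized nucleosome metagene over midpoint ± 1 kb.

    Each peak's binned density is divided by that peak's total count in
    the window, so deeply and shallowly covered loci contribute equally;
    the per-peak profiles are then averaged and smoothed with an N = 5
    moving average. ``mode`` selects full-fragment coverage (default,
    following single-fragment conversion of paired reads) or fragment
    midpoints (a dyad-position proxy). Peaks with zero signal in the
    window are dropped and returned.

    Returns ``(MetageneProfile, dropped_peak_ids)``.
    """
    params = params or Parameters()
    if track is None:
        if genome is None:
            raise ValidationError("mnase_metagene needs a genome or a prebuilt track")
        if mode == "coverage":
            track = coverage_track(fragments, genome)
        elif mode == "midpoint":
            track = midpoint_track(fragments, genome)
        else:
            raise ValidationError(f"unknown mode {mode!r}")
    window = 2 * params.flank_window_bp
    matrix = profile_matrix(track, peaks, window, params.metagene_bin_bp)
    totals = matrix.values.sum(axis=1) * matrix.bin_bp
    keep = totals > 0
    dropped = [pid for pid, k in zip(matrix.peak_ids, keep) if not k]
    if dropped:
        logger.warning("mnase_metagene: dropped %d zero-signal peaks", len(dropped))
    if not keep.any():
        raise ValidationError("all peaks have zero signal in the profiling window")
    normalized = matrix.values[keep] / totals[keep, None]
    mean = normalized.mean(axis=0)
    smoothed = moving_average(mean, params.moving_average_n)
    return MetageneProfile(matrix.offsets, smoothed, int(keep.sum())), dropped


def order_rows(
    matrix: ProfileMatrix,
    atac_track: SignalTrack,
    peaks: PeakSet,
    classes: dict,
    sigma_bp: float = 250.0,
    flank_bp: int = 1000,
) -> list:
    """Heatmap row order: class blocks G1..G4, each sorted by decreasing
    Gaussian-weighted (sigma = 250 bp) ATAC signal around the midpoint;
    ties break by peak id."""
    missing = [pid for pid in matrix.peak_ids if pid not in classes]
    if missing:
        raise ValidationError(f"unclassified peaks: {missing[:3]}...")
    mid_by_id = dict(zip(peaks.df["id"], peaks.df["midpoint"]))
    chrom_by_id = dict(zip(peaks.df["id"], peaks.df["chrom"]))
    weighted = {}
    for pid in matrix.peak_ids:
        chrom, mid = chrom_by_id[pid], mid_by_id[pid]
        pos = atac_track.positions(chrom)
        val = atac_track.values(chrom)
        i0, i1 = np.searchsorted(pos, [mid - flank_bp, mid + flank_bp])
        d = pos[i0:i1] - mid
        weighted[pid] = float(np.sum(val[i0:i1] * np.exp(-(d**2) / (2 * sigma_bp**2))))
    order = []
    for cls in ("G1", "G2", "G3", "G4"):
        block = [pid for pid in matrix.peak_ids if classes[pid] == cls]
        block.sort(key=lambda pid: (-weighted[pid], pid))
        order.extend(block)
    return order


@dataclass
class GroupComparison:
    box_stats: pd.DataFrame  # per class: n, median, mean, p5, p95
    pairwise_p: pd.DataFrame  # symmetric matrix of two-sided rank-sum p-values


def compare_groups(values_by_class: dict) -> GroupComparison:
    """Box statistics and pairwise two-sided Mann-Whitney tests.

    Exact enumeration when both groups have n <= 8 and no ties span the
    groups; normal approximation with tie correction otherwise.
    """
    for cls, vals in values_by_class.items():
        if len(vals) < 2:
            raise ValidationError(f"group {cls!r} has fewer than 2 values")
    names = list(values_by_class)
    stats_rows = []
    for cls in names:
        v = np.asarray(values_by_class[cls], dtype=float)
        stats_rows.append(
            {
                "class": cls,
                "n": len(v),
                "median": float(np.median(v)),
                "mean": float(v.mean()),
                "p5": float(np.percentile(v, 5)),
                "p95": float(np.percentile(v, 95)),
            }
        )
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va = np.asarray(values_by_class[a], dtype=float)
            vb = np.asarray(values_by_class[b], dtype=float)
            has_ties = len(np.unique(np.concatenate([va, vb]))) < len(va) + len(vb)
            method = "exact" if (len(va) <= 8 and len(vb) <= 8 and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method)
            pmat.loc[a, b] = pmat.loc[b, a] = float(res.pvalue)
    return GroupComparison(pd.DataFrame(stats_rows), pmat)
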