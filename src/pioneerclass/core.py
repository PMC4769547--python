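"""Core data model for interval-level chromatin data.

Genomic coordinates are 0-based half-open (BED convention) throughout.
Fragments and reads are carried in array-backed containers so that
multi-million-row libraries stay vectorized; per-base signal is stored
sparsely (sorted position / value arrays per chromosome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSAYS = ("ATAC", "MNASE", "CHIP")
FRAGMENT_COLUMNS = ("chrom", "start", "end", "strand")


class ValidationError(ValueError):
    """Raised when genomic records violate coordinate invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A named binding-site interval; the midpoint anchors all profiling."""

    id: str
    interval: GenomicInterval

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


class PeakSet:
    """Ordered collection of peaks with unique ids (DataFrame-backed)."""

    def __init__(self, df: pd.DataFrame):
        required = {"id", "chrom", "start", "end"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"PeakSet missing columns: {sorted(missing)}")
        df = df.reset_index(drop=True).copy()
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValidationError(f"duplicate peak id: {dup!r}")
        if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            raise ValidationError("peak coordinates violate 0 <= start < end")
        df["midpoint"] = (df["start"] + df["end"]) // 2
        self.df = df

    @classmethod
    def from_peaks(cls, peaks) -> "PeakSet":
        rows = [
            {"id": p.id, "chrom": p.chrom, "start": p.start, "end": p.end}
            for p in peaks
        ]
        return cls(pd.DataFrame(rows, columns=["id", "chrom", "start", "end"]))

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Peak(row.id, GenomicInterval(row.chrom, int(row.start), int(row.end)))

    def subset(self, ids) -> "PeakSet":
        wanted = set(ids)
        return PeakSet(self.df[self.df["id"].isin(wanted)].drop(columns=["midpoint"]))


@dataclass
class FragmentSet:
    """Strand-aware fragments/reads for one assay and condition.

    ``df`` holds columns (chrom, start, end, strand); replicate merging is
    plain concatenation (`FragmentSet.concat`).
    """

    assay: str
    condition: str
    df: pd.DataFrame
    is_paired: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}; expected {ASSAYS}")
        df = self.df.reset_index(drop=True)
        for col in FRAGMENT_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"FragmentSet missing column {col!r}")
        if len(df):
            if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
                raise ValidationError("fragment coordinates violate 0 <= start < end")
        self.df = df[list(FRAGMENT_COLUMNS)]

    @property
    def total_count(self) -> int:
        return len(self.df)

    @classmethod
    def concat(cls, sets) -> "FragmentSet":
        sets = list(sets)
        first = sets[0]
        for s in sets[1:]:
            if (s.assay, s.condition) != (first.assay, first.condition):
                raise ValidationError("can only merge replicates of one assay/condition")
        return cls(
            first.assay,
            first.condition,
            pd.concat([s.df for s in sets], ignore_index=True),
            is_paired=first.is_paired,
        )


def deduplicate(fragments: FragmentSet) -> FragmentSet:
    """Collapse records with identical (chrom, start, end, strand) to one copy."""
    df = fragments.df.drop_duplicates(subset=list(FRAGMENT_COLUMNS), keep="first")
    n_removed = fragments.total_count - len(df)
    out = FragmentSet(
        fragments.assay,
        fragments.condition,
        df,
        is_paired=fragments.is_paired,
        meta=dict(fragments.meta),
    )
    out.meta["duplicates_removed"] = n_removed
    return out


@dataclass
class Parameters:
    """The pipeline's tunable constants.

    Defaults follow the study design this package models: FDR < 0.1 and
    fold change > 2 for accessibility change, a 200 bp counting window on
    the peak midpoint, a 20-count open/closed cutoff in the ±1 kb flank,
    normalization to 30 million total reads, and N=5 moving-average
    smoothing of nucleosome profiles.
    """

    fdr_threshold: float = 0.1
    fold_change_threshold: float = 2.0
    count_window_bp: int = 200
    flank_window_bp: int = 1000
    open_count_cutoff: float = 20.0
    normalization_target: float = 30_000_000.0
    moving_average_n: int = 5
    heatmap_window_bp: int = 10_000
    tss_proximal_bp: int = 1000
    metagene_bin_bp: int = 10
    heatmap_bin_bp: int = 100
    dispersion: float = 0.1
    max_slide_lag_bp: int = 90

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "dispersion":
                if v < 0:
                    raise ValidationError("dispersion must be >= 0")
            elif v <= 0:
                raise ValidationError(f"{f.name} must be > 0 (got {v})")
        if self.moving_average_n % 2 == 0:
            raise ValidationError("moving_average_n must be odd")


class SignalTrack:
    """Sparse per-base signal over a genome.

    Positions with zero signal are not stored. Values are raw tag/cut
    counts until `normalize` rescales them to a target total.
    """

    def __init__(self, genome: dict, normalization_target: float | None = None):
        if not genome:
            raise ValidationError("genome must map chrom -> length")
        self.genome = {str(c): int(l) for c, l in genome.items()}
        self.normalization_target = normalization_target
        self._pos: dict[str, np.ndarray] = {}
        self._val: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}  # cumulative sums for window queries

    # -- construction -------------------------------------------------

    @classmethod
    def from_positions(cls, genome, chroms, positions, weights=None) -> "SignalTrack":
        """Build a track from per-event base positions (e.g. cut sites)."""
        track = cls(genome)
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        if weights is None:
            weights = np.ones(len(positions))
        weights = np.asarray(weights, dtype=float)
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            pos = positions[sel]
            uniq, inv = np.unique(pos, return_inverse=True)
            val = np.zeros(len(uniq))
            np.add.at(val, inv, weights[sel])
            track._set(str(chrom), uniq, val)
        return track

    @classmethod
    def from_dense(cls, genome, dense: dict) -> "SignalTrack":
        """Build from dense per-chromosome arrays, dropping zeros."""
        track = cls(genome)
        for chrom, arr in dense.items():
            arr = np.asarray(arr, dtype=float)
            nz = np.nonzero(arr)[0]
            track._set(chrom, nz.astype(np.int64), arr[nz])
        return track

    def _set(self, chrom, pos, val):
        if chrom not in self.genome:
            raise ValidationError(f"chromosome {chrom!r} not in genome")
        if len(pos) and (pos[-1] >= self.genome[chrom] or pos[0] < 0):
            raise ValidationError(f"positions outside {chrom} bounds")
        if np.any(val < 0):
            raise ValidationError("track values must be >= 0")
        self._pos[chrom] = pos
        self._val[chrom] = val
        self._cum[chrom] = np.concatenate(([0.0], np.cumsum(val)))

    # -- queries ------------------------------------------------------

    @property
    def chroms(self):
        return list(self._pos)

    def total(self) -> float:
        return float(sum(c[-1] for c in self._cum.values())) if self._cum else 0.0

    def positions(self, chrom):
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def values(self, chrom):
        return self._val.get(chrom, np.empty(0))

    def counts_in_windows(self, chrom, centers, halfwidth: int) -> np.ndarray:
        """Vectorized sum over [center - halfwidth, center + halfwidth)."""
        if halfwidth <= 0:
            raise ValidationError("halfwidth must be > 0")
        centers = np.atleast_1d(np.asarray(centers, dtype=np.int64))
        if chrom not in self._pos:
            return np.zeros(len(centers))
        length = self.genome[chrom]
        lo = np.clip(centers - halfwidth, 0, length)
        hi = np.clip(centers + halfwidth, 0, length)
        pos, cum = self._pos[chrom], self._cum[chrom]
        return cum[np.searchsorted(pos, hi)] - cum[np.searchsorted(pos, lo)]

    def window_profile(self, chrom, center, window_bp, bin_bp) -> np.ndarray:
        """Binned density (per bp) over [center - w/2, center + w/2).

        Bins outside the chromosome are zero-padded.
        """
        if window_bp % bin_bp:
            raise ValidationError("window_bp must be divisible by bin_bp")
        n_bins = window_bp // bin_bp
        out = np.zeros(n_bins)
        if chrom not in self._pos:
            return out
        left = int(center) - window_bp // 2
        pos, val = self._pos[chrom], self._val[chrom]
        i0, i1 = np.searchsorted(pos, [left, left + window_bp])
        if i1 > i0:
            bins = (pos[i0:i1] - left) // bin_bp
            np.add.at(out, bins, val[i0:i1])
        return out / bin_bp


def normalize(track: SignalTrack, target: float | None = None) -> SignalTrack:
    """Scale every value by target/total so that the new total equals target."""
    if target is None:
        target = Parameters().normalization_target
    total = track.total()
    if total <= 0:
        raise ValidationError("cannot normalize empty track")
    scale = target / total
    out = SignalTrack(track.genome, normalization_target=float(target))
    for chrom in track.chroms:
        out._set(chrom, track.positions(chrom).copy(), track.values(chrom) * scale)
    return out


def count_in_window(track: SignalTrack, chrom: str, center: int, halfwidth: int) -> float:
    """Sum of track values in [center - halfwidth, center + halfwidth)."""
    return float(track.counts_in_windows(chrom, [center], halfwidth)[0])


def tn5_cut_sites(
    fragments: FragmentSet,
    genome: dict,
    shift_plus: int = 4,
    shift_minus: int = 5,
) -> SignalTrack:
    """Transposase cut-site track with insertion-offset correction.

    Tn5 inserts as a dimer, so the sequenced 5' ends sit off the true
    insertion point; plus-strand ends are shifted +4 bp and minus-strand
    ends -5 bp (applied to the half-open end coordinate). Paired
    fragments contribute both ends; single-end reads one end according
    to strand. Shifted positions falling outside the chromosome are
    clipped to its bounds and tallied in ``track.n_clipped``.
    """
    if fragments.assay != "ATAC":
        raise ValidationError("tn5_cut_sites expects an ATAC FragmentSet")
    df = fragments.df
    if fragments.is_paired:
        chroms = np.concatenate([df["chrom"].to_numpy()] * 2)
        sites = np.concatenate(
            [df["start"].to_numpy() + shift_plus, df["end"].to_numpy() - shift_minus]
        )
    else:
        plus = df["strand"].to_numpy() != "-"
        sites = np.where(
            plus,
            df["start"].to_numpy() + shift_plus,
            df["end"].to_numpy() - shift_minus,
        )
        chroms = df["chrom"].to_numpy()
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    clipped = (sites < 0) | (sites >= lengths)
    n_clipped = int(clipped.sum())
    if n_clipped:
        sites = np.clip(sites, 0, lengths - 1)
    track = SignalTrack.from_positions(genome, chroms, sites)
    track.n_clipped = n_clipped
    return track


def coverage_track(fragments: FragmentSet, genome: dict) -> SignalTrack:
    """Per-base full-fragment coverage (each fragment covers [start, end))."""
    dense = {}
    for chrom, sub in fragments.df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise ValidationError(f"chromosome {chrom!r} not in genome")
        length = genome[chrom]
        diff = np.zeros(length + 1)
        np.add.at(diff, np.clip(sub["start"].to_numpy(), 0, length), 1.0)
        np.add.at(diff, np.clip(sub["end"].to_numpy(), 0, length), -1.0)
        dense[chrom] = np.cumsum(diff)[:length]
    return SignalTrack.from_dense(genome, dense)


def midpoint_track(fragments: FragmentSet, genome: dict) -> SignalTrack:
    """One count per fragment at its midpoint (dyad proxy for nucleosomal data)."""
    df = fragments.df
    mids = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    return SignalTrack.from_positions(genome, df["chrom"].to_numpy(), mids)
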