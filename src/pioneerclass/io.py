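"""Readers and writers for the plain-text formats the pipeline consumes.

Supported inputs: BED3/BED6 (peaks, single-end reads), BEDPE (paired
fragments, mates collapsed to one spanning fragment), two-column
chrom-sizes text. Outputs: BED6, BEDPE, bedGraph, TSV tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FragmentSet, PeakSet, SignalTrack, ValidationError

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def read_chrom_sizes(path) -> dict:
    genome = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{i}: expected 'chrom<TAB>length'")
            try:
                genome[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: bad length {parts[1]!r}") from exc
    if not genome:
        raise ParseError(f"{path}: empty chrom sizes file")
    return genome


def read_peaks(path) -> PeakSet:
    """Read BED3/BED6 peaks; ids from column 4 or generated as peak_<n>."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{i}: expected at least 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise ValidationError(
                    f"{path}:{i}: invalid interval {parts[0]}:{start}-{end}"
                )
            name = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else f"peak_{len(rows) + 1}"
            rows.append({"id": name, "chrom": parts[0], "start": start, "end": end})
    if not rows:
        logger.warning("%s: no peaks found; returning empty PeakSet", path)
        return PeakSet(pd.DataFrame(columns=["id", "chrom", "start", "end"]))
    return PeakSet(pd.DataFrame(rows))


def _looks_paired(path) -> bool:
    """BEDPE detection: column 4 is a chromosome (mate 2) and cols 5-6 integers."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 6:
                try:
                    int(parts[4]), int(parts[5])
                except ValueError:
                    return False
                try:
                    int(parts[3])
                    return False  # numeric col 4 is a BED score-like field
                except ValueError:
                    return True
            return False
    return False


def read_fragments(path, assay: str, condition: str, paired: bool | None = None) -> FragmentSet:
    """Read a fragment library from BED6 (single-end) or BEDPE (paired).

    Paired mates are collapsed to a single fragment spanning
    min(start) .. max(end); interchromosomal pairs are skipped and
    counted in ``meta['skipped_interchromosomal']``.
    """
    path = Path(path)
    if paired is None:
        paired = path.suffix == ".bedpe" or _looks_paired(path)
    if paired:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=range(6),
            names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
            dtype={"chrom1": str, "chrom2": str},
        )
        same = df["chrom1"] == df["chrom2"]
        n_skipped = int((~same).sum())
        if n_skipped:
            logger.warning("%s: skipped %d interchromosomal pairs", path, n_skipped)
        df = df[same]
        out = pd.DataFrame(
            {
                "chrom": df["chrom1"],
                "start": df[["start1", "start2"]].min(axis=1),
                "end": df[["end1", "end2"]].max(axis=1),
                "strand": ".",
            }
        )
        frags = FragmentSet(assay, condition, out, is_paired=True)
        frags.meta["skipped_interchromosomal"] = n_skipped
        return frags
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
        dtype={"chrom": str, "strand": str},
    )
    out = df[["chrom", "start", "end", "strand"]].copy()
    out["strand"] = out["strand"].fillna(".")
    return FragmentSet(assay, condition, out, is_paired=False)


def write_fragments(fragments: FragmentSet, path) -> None:
    """Write single-end fragments as BED6 or paired fragments as BEDPE mates."""
    df = fragments.df
    if fragments.is_paired:
        # emit 36 bp mates at the fragment extremities
        mate = np.minimum(36, df["end"] - df["start"])
        out = pd.DataFrame(
            {
                "chrom1": df["chrom"], "start1": df["start"], "end1": df["start"] + mate,
                "chrom2": df["chrom"], "start2": df["end"] - mate, "end2": df["end"],
            }
        )
    else:
        out = pd.DataFrame(
            {
                "chrom": df["chrom"], "start": df["start"], "end": df["end"],
                "name": ".", "score": 0, "strand": df["strand"],
            }
        )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_peaks(peaks: PeakSet, path) -> None:
    peaks.df[["chrom", "start", "end", "id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write the sparse track as bedGraph, merging runs of equal adjacent values."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            pos = track.positions(chrom)
            val = track.values(chrom)
            if not len(pos):
                continue
            # run boundaries: position gap or value change
            brk = np.nonzero((np.diff(pos) != 1) | (np.diff(val) != 0))[0] + 1
            starts = np.concatenate(([0], brk))
            ends = np.concatenate((brk, [len(pos)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{pos[s]}\t{pos[e - 1] + 1}\t{val[s]:.6g}\n")


def write_chrom_sizes(genome: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")
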