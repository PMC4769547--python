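"""Differential-accessibility classification of TF binding sites.

Peaks are split into four classes from two-condition ATAC signal:

* **G1** — accessibility gained (FDR < 0.1, fold change > 2 upward): the
  pioneer class, previously closed chromatin opened by the factor.
* **G2** — conserved and pre-open (control ±1 kb flank count >= 20).
* **G3** — conserved and closed (flank count < 20): bound but
  transposase-inaccessible, nucleosome-embedded sites.
* **G4** — accessibility lost (FDR < 0.1, fold change > 2 downward).

The differential test is an exact conditional rate test: with the two
libraries normalized to the same total, the count in condition A given
the window total follows a binomial (dispersion 0) or an overdispersed
negative-binomial conditional law (dispersion > 0), and the two-sided
p-value doubles the smaller tail. A fixed dispersion stands in for a
replicate-estimated one because replicates are merged upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Parameters, PeakSet, SignalTrack, ValidationError

CLASSES = ("G1", "G2", "G3", "G4")


@dataclass(frozen=True)
class CountRecord:
    peak_id: str
    count_control_200bp: float
    count_treated_200bp: float
    count_control_flank2kb: float

    def __post_init__(self):
        if min(self.count_control_200bp, self.count_treated_200bp,
               self.count_control_flank2kb) < 0:
            raise ValidationError("counts must be >= 0")


@dataclass(frozen=True)
class PeakClassification:
    peak_id: str
    p_value: float
    fdr: float
    log2_fold_change: float
    peak_class: str
    tss_distance: int | None = None
    tss_label: str | None = None


def build_count_matrix(
    peaks: PeakSet,
    atac_control: SignalTrack,
    atac_treated: SignalTrack,
    params: Parameters | None = None,
) -> list[CountRecord]:
    """Windowed normalized counts per peak: midpoint ± 100 bp in both
    conditions and the control midpoint ± 1 kb flank."""
    params = params or Parameters()
    half = params.count_window_bp // 2
    flank = params.flank_window_bp
    records: dict[int, CountRecord] = {}
    for chrom, sub in peaks.df.groupby("chrom", sort=False):
        mids = sub["midpoint"].to_numpy()
        c200 = atac_control.counts_in_windows(chrom, mids, half)
        t200 = atac_treated.counts_in_windows(chrom, mids, half)
        cflank = atac_control.counts_in_windows(chrom, mids, flank)
        for idx, pid, a, b, c in zip(sub.index, sub["id"], c200, t200, cflank):
            records[idx] = CountRecord(pid, float(a), float(b), float(c))
    return [records[i] for i in range(len(peaks))]


def exact_rate_test(
    x_a: float, x_b: float, n_a: float, n_b: float, dispersion: float = 0.0
) -> float:
    """Two-sided exact test for equality of rates between two libraries.

    Counts are rounded to integers and the test conditions on the window
    total N = x_a + x_b. With ``dispersion`` 0 the conditional law of
    x_a is Binomial(N, n_a / (n_a + n_b)); with dispersion phi > 0 the
    conditional law is obtained by enumerating k = 0..N with weights
    NB(k; mu_a, phi) * NB(N - k; mu_b, phi) where mu_a = N * pi. The
    two-sided p-value doubles the smaller tail (point included), capped
    at 1.
    """
    if x_a < 0 or x_b < 0:
        raise ValidationError("counts must be >= 0")
    if n_a <= 0 or n_b <= 0:
        raise ValidationError("library totals must be > 0")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    xa = int(round(x_a))
    xb = int(round(x_b))
    n = xa + xb
    if n == 0:
        return 1.0
    pi = n_a / (n_a + n_b)
    if dispersion == 0:
        lower = stats.binom.cdf(xa, n, pi)
        upper = stats.binom.sf(xa - 1, n, pi)
    else:
        k = np.arange(n + 1)
        r = 1.0 / dispersion
        mu_a, mu_b = n * pi, n * (1 - pi)
        logw = stats.nbinom.logpmf(k, r, r / (r + mu_a)) + stats.nbinom.logpmf(
            n - k, r, r / (r + mu_b)
        )
        w = np.exp(logw - logw.max())
        w /= w.sum()
        lower = float(w[: xa + 1].sum())
        upper = float(w[xa:].sum())
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def classify_peaks(
    records: list[CountRecord], params: Parameters | None = None
) -> list[PeakClassification]:
    """Assign each peak exactly one class G1-G4.

    Fold change uses a 0.5 pseudocount per side on the normalized
    counts; thresholds are strict (> / <) so exact ties fall into the
    conserved classes.
    """
    params = params or Parameters()
    target = params.normalization_target
    p_values = np.array(
        [
            exact_rate_test(
                r.count_control_200bp,
                r.count_treated_200bp,
                target,
                target,
                params.dispersion,
            )
            for r in records
        ]
    )
    fdrs = bh_fdr(p_values)
    out = []
    for rec, p, fdr in zip(records, p_values, fdrs):
        fc = (rec.count_treated_200bp + 0.5) / (rec.count_control_200bp + 0.5)
        log2fc = float(np.log2(fc))
        if fdr < params.fdr_threshold and fc > params.fold_change_threshold:
            cls = "G1"
        elif fdr < params.fdr_threshold and 1.0 / fc > params.fold_change_threshold:
            cls = "G4"
        elif rec.count_control_flank2kb >= params.open_count_cutoff:
            cls = "G2"
        else:
            cls = "G3"
        out.append(PeakClassification(rec.peak_id, float(p), float(fdr), log2fc, cls))
    return out


def annotate_tss(peaks: PeakSet, tss: pd.DataFrame, proximal_bp: int = 1000):
    """Distance from each peak midpoint to the nearest TSS and the
    proximal (distance <= 1 kb) / distal (> 1 kb) label.

    ``tss`` needs columns (chrom, pos). Peaks on chromosomes without a
    TSS fall back to the global list (distance from any chromosome is
    meaningless, so the minimum over same-chromosome TSS is preferred
    whenever one exists).
    """
    if tss is None or len(tss) == 0:
        raise ValidationError("TSS list is empty")
    by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy()) for chrom, sub in tss.groupby("chrom")
    }
    global_pos = np.sort(tss["pos"].to_numpy())
    results = []
    for row in peaks.df.itertuples(index=False):
        positions = by_chrom.get(row.chrom, global_pos)
        i = np.searchsorted(positions, row.midpoint)
        cand = positions[max(0, i - 1): i + 1]
        dist = int(np.min(np.abs(cand - row.midpoint)))
        label = "proximal" if dist <= proximal_bp else "distal"
        results.append((dist, label))
    return results


@dataclass(frozen=True)
class OverlapResult:
    shared_a: list
    shared_b: list
    unique_a: list
    unique_b: list

    @property
    def counts(self):
        return {
            "shared_a": len(self.shared_a),
            "shared_b": len(self.shared_b),
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
        }


def overlap_peaks(set_a: PeakSet, set_b: PeakSet) -> OverlapResult:
    """Partition two peak sets by >= 1 bp interval overlap (Venn counts)."""

    def shared_mask(query: PeakSet, subject: PeakSet) -> np.ndarray:
        mask = np.zeros(len(query), dtype=bool)
        groups = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
            for chrom, sub in subject.df.groupby("chrom")
        }
        for i, row in enumerate(query.df.itertuples(index=False)):
            entry = groups.get(row.chrom)
            if entry is None:
                continue
            starts, ends = entry
            mask[i] = bool(np.any((starts < row.end) & (ends > row.start)))
        return mask

    mask_a = shared_mask(set_a, set_b)
    mask_b = shared_mask(set_b, set_a)
    ids_a, ids_b = set_a.ids, set_b.ids
    return OverlapResult(
        shared_a=list(ids_a[mask_a]),
        shared_b=list(ids_b[mask_b]),
        unique_a=list(ids_a[~mask_a]),
        unique_b=list(ids_b[~mask_b]),
    )


def classification_table(
    peaks: PeakSet,
    records: list[CountRecord],
    classifications: list[PeakClassification],
) -> pd.DataFrame:
    """Flat result table (one row per peak) for TSV export."""
    rows = []
    for peak_row, rec, cls in zip(peaks.df.itertuples(index=False), records, classifications):
        rows.append(
            {
                "peak_id": cls.peak_id,
                "chrom": peak_row.chrom,
                "start": peak_row.start,
                "end": peak_row.end,
                "count_ctrl": rec.count_control_200bp,
                "count_treat": rec.count_treated_200bp,
                "count_ctrl_flank": rec.count_control_flank2kb,
                "log2FC": cls.log2_fold_change,
                "p_value": cls.p_value,
                "fdr": cls.fdr,
                "class": cls.peak_class,
                "tss_distance": cls.tss_distance,
                "tss_label": cls.tss_label,
            }
        )
    return pd.DataFrame(rows)
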