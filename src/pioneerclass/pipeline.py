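"""High-level stage functions chaining the core modules.

These are the library entry points the CLI wraps: fragments in,
classification / profile / dynamics tables out. Every function is a
pure function of its inputs, so reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from . import classify as pc
from .core import (
    FragmentSet,
    Parameters,
    PeakSet,
    SignalTrack,
    coverage_track,
    deduplicate,
    midpoint_track,
    normalize,
    tn5_cut_sites,
)
from .dynamics import dynamics_table, stability_analysis
from .profiles import metagene, mnase_metagene, profile_matrix


def atac_cut_track(
    fragments: FragmentSet, genome: dict, norm_target: float, dedup: bool = False
) -> SignalTrack:
    """ATAC preprocessing: optional coordinate dedup, Tn5 offset
    correction, cut-site pileup, depth normalization."""
    if dedup:
        fragments = deduplicate(fragments)
    return normalize(tn5_cut_sites(fragments, genome), norm_target)


def classify_dataset(
    peaks: PeakSet,
    atac_control: FragmentSet,
    atac_treated: FragmentSet,
    genome: dict,
    params: Parameters | None = None,
    norm_target: float | None = None,
    tss: pd.DataFrame | None = None,
    dedup: bool = False,
) -> pd.DataFrame:
    """Full classification stage: fragments -> per-peak class table."""
    params = params or Parameters()
    if norm_target is not None:
        params = replace(params, normalization_target=float(norm_target))
    track_c = atac_cut_track(atac_control, genome, params.normalization_target, dedup)
    track_t = atac_cut_track(atac_treated, genome, params.normalization_target, dedup)
    records = pc.build_count_matrix(peaks, track_c, track_t, params)
    classifications = pc.classify_peaks(records, params)
    if tss is not None and len(tss):
        annotations = pc.annotate_tss(peaks, tss, params.tss_proximal_bp)
        classifications = [
            replace(c, tss_distance=d, tss_label=lab)
            for c, (d, lab) in zip(classifications, annotations)
        ]
    return pc.classification_table(peaks, records, classifications)


def class_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Class counts and percentages (the classification headline)."""
    counts = table["class"].value_counts().reindex(pc.CLASSES, fill_value=0)
    return pd.DataFrame(
        {
            "class": counts.index,
            "n_peaks": counts.to_numpy(),
            "percent": (100 * counts / max(len(table), 1)).round(2).to_numpy(),
        }
    )


def classes_from_table(table: pd.DataFrame) -> dict:
    return dict(zip(table["peak_id"], table["class"]))


def peaks_from_table(table: pd.DataFrame) -> PeakSet:
    return PeakSet(table[["peak_id", "chrom", "start", "end"]].rename(columns={"peak_id": "id"}))


def metagene_by_class(
    track: SignalTrack,
    peaks: PeakSet,
    classes: dict,
    window_bp: int,
    bin_bp: int,
) -> dict:
    """Per-class metagene profiles of an arbitrary normalized track."""
    matrix = profile_matrix(track, peaks, window_bp, bin_bp)
    out = {}
    for cls in pc.CLASSES:
        ids = [pid for pid in matrix.peak_ids if classes.get(pid) == cls]
        if ids:
            out[cls] = metagene(matrix, ids)
    return out


def mnase_profiles_by_class(
    fragments: FragmentSet,
    peaks: PeakSet,
    classes: dict,
    genome: dict,
    params: Parameters | None = None,
    mode: str = "coverage",
) -> dict:
    """Per-class per-locus-normalized nucleosome metagenes (one shared
    coverage track, per-class averaging)."""
    params = params or Parameters()
    track = (coverage_track if mode == "coverage" else midpoint_track)(fragments, genome)
    out = {}
    for cls in pc.CLASSES:
        ids = [pid for pid in peaks.ids if classes.get(pid) == cls]
        if not ids:
            continue
        profile, _dropped = mnase_metagene(
            fragments, peaks.subset(ids), params, mode=mode, track=track
        )
        out[cls] = profile
    return out


def dynamics_from_mnase(
    mnase_control: FragmentSet,
    mnase_treated: FragmentSet,
    peaks: PeakSet,
    classes: dict,
    genome: dict,
    params: Parameters | None = None,
    mode: str = "coverage",
) -> pd.DataFrame:
    """Class-level eviction / phasing / sliding table from two-condition
    MNase fragments."""
    params = params or Parameters()
    prof_c = mnase_profiles_by_class(mnase_control, peaks, classes, genome, params, mode)
    prof_t = mnase_profiles_by_class(mnase_treated, peaks, classes, genome, params, mode)
    common = {c: prof_c[c] for c in prof_c if c in prof_t}
    return dynamics_table(common, {c: prof_t[c] for c in common}, params)


def thermal_stability(
    chip_37c: FragmentSet,
    chip_ice: FragmentSet,
    peaks: PeakSet,
    classes: dict,
    genome: dict,
    norm_target: float,
):
    """Thermal-challenge ChIP comparison on midpoint tag-density tracks."""
    t_hot = normalize(midpoint_track(chip_37c, genome), norm_target)
    t_ice = normalize(midpoint_track(chip_ice, genome), norm_target)
    return stability_analysis(t_hot, t_ice, peaks, classes)
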