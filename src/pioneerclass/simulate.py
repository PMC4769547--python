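"""Synthetic two-condition chromatin data with planted architectures.

A single synthetic chromosome carries peaks in four planted classes
mirroring the chromatin outcomes at pioneer-factor binding sites:

* G1 — nucleosome over the site in control; in the treated condition the
  central nucleosome is evicted and the flanking nucleosomes become a
  phased array; accessibility is gained.
* G2 — nucleosome-depleted region flanked by positioned nucleosomes in
  both conditions (pre-open sites).
* G3 — regular nucleosome array over the site in both conditions; the
  treated array is slid by a fixed offset; no accessibility. TF ChIP
  enrichment is lower than at G1/G2, and a thermal-challenge ChIP
  condition destabilizes binding only here.
* G4 — the reverse of G1: open chromatin closes.

MNase fragments are sampled with probability proportional to the
nucleosome-occupancy landscape plus a uniform background; ATAC cut
sites follow an accessibility landscape (inverse occupancy at open
windows over a uniform floor); ChIP fragments follow factor-specific
placement rules. All outputs are pure functions of (config, seed).

The planted eviction fraction is defined on the observable scale: the
fractional drop of per-locus-normalized central MNase density between
conditions. The generator solves the corresponding center-nucleosome
weight by root-finding on its own analytic expected profile, so the
planted value and the estimand coincide by construction (see
docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .core import FragmentSet, Parameters, PeakSet, ValidationError
from .profiles import MetageneProfile, bin_offsets, moving_average

logger = logging.getLogger(__name__)

CLASSES = ("G1", "G2", "G3", "G4")
CHIP_FACTORS = ("TF", "H3K4me1", "H3K27ac", "cofactor")

# reference genome size implied by the normalization constants the
# analysis defaults emulate (30 M reads over a ~3.1 Gb genome)
_REFERENCE_GENOME_BP = 3.1e9

# rng stream ids so every assay/condition draws independent,
# reproducible substreams of the one config seed
_STREAMS = {
    "layout": 0,
    ("ATAC", "control"): 10,
    ("ATAC", "treated"): 11,
    ("MNASE", "control"): 20,
    ("MNASE", "treated"): 21,
    ("TF", "control", "ice"): 30,
    ("TF", "treated", "ice"): 31,
    ("TF", "control", "37C"): 32,
    ("TF", "treated", "37C"): 33,
    ("H3K4me1", "control", "ice"): 40,
    ("H3K4me1", "treated", "ice"): 41,
    ("H3K27ac", "control", "ice"): 42,
    ("H3K27ac", "treated", "ice"): 43,
    ("cofactor", "control", "ice"): 44,
    ("cofactor", "treated", "ice"): 45,
}


def _rng(seed: int, stream) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic chromosome.

    200 peaks per class on a 2 Mb chromosome keeps rank tests stable
    while the whole pipeline runs in seconds; nucleosome geometry uses
    the canonical 147 bp footprint and a 190 bp repeat length.
    """

    genome_length: int = 2_000_000
    chrom: str = "chrS"
    n_peaks_per_class: int | dict = 200
    peak_halfwidth: int = 100
    edge_margin: int = 5_000
    nucleosome_spacing: int = 190
    footprint: int = 147
    n_flank_nucleosomes: int = 5
    dyad_sd: float = 10.0
    fragment_length_sd: float = 10.0
    depth_atac: int = 1_500_000
    depth_mnase: int = 1_000_000
    depth_chip: int = 200_000
    eviction_fraction: float = 0.8
    slide_bp: int = 50
    accessibility_fold: float = 30.0
    tf_enrichment: float = 8.0
    g3_tf_multiplier: float = 0.5
    thermal_destabilization_factor: float = 0.4
    mnase_background: float = 0.10
    chip_background: float = 0.15
    atac_read_length: int = 36
    chip_fragment_length: int = 200
    tss_proximal_fraction: float = 0.3
    seed: int = 0

    def class_counts(self) -> dict:
        if isinstance(self.n_peaks_per_class, dict):
            return {cls: int(self.n_peaks_per_class.get(cls, 0)) for cls in CLASSES}
        return {cls: int(self.n_peaks_per_class) for cls in CLASSES}

    @property
    def n_peaks(self) -> int:
        return sum(self.class_counts().values())

    @property
    def norm_target(self) -> float:
        """Normalization target that keeps windowed counts on the scale of
        a 30 M-read genome-wide library (so the 20-count open/closed
        cutoff keeps its meaning on a miniature genome)."""
        return float(round(30e6 * self.genome_length / _REFERENCE_GENOME_BP))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["norm_target"] = self.norm_target
        return d


# ---------------------------------------------------------------------------
# planted layout
# ---------------------------------------------------------------------------

@dataclass
class Layout:
    """Planted ground truth: peaks, per-peak generative parameters, TSS."""

    config: SimulationConfig
    peaks: PeakSet
    truth: pd.DataFrame
    tss: pd.DataFrame
    center_weight: float  # solved evicted-center nucleosome weight

    def classes(self) -> dict:
        return dict(zip(self.truth["peak_id"], self.truth["class"]))


def plant_layout(config: SimulationConfig) -> Layout:
    """Place peaks (deterministic for the seed) and build the truth table.

    Peaks are laid out on a jittered grid; the spacing must leave the
    ±1 kb planted architectures disjoint, otherwise the genome is
    declared overcrowded.
    """
    cfg = config
    counts = cfg.class_counts()
    n = cfg.n_peaks
    if n == 0:
        raise ValidationError("no peaks requested")
    avail = cfg.genome_length - 2 * cfg.edge_margin
    spacing = avail / n
    min_spacing = 2 * (Parameters().flank_window_bp) + 100
    if spacing < min_spacing:
        raise ValidationError(
            f"overcrowded genome: spacing {spacing:.0f} bp < {min_spacing} bp "
            f"needed for non-overlapping planted architectures"
        )
    rng = _rng(cfg.seed, "layout")
    jitter_max = min(200.0, (spacing - min_spacing) / 2)
    mids = cfg.edge_margin + (np.arange(n) + 0.5) * spacing
    mids = np.round(mids + rng.uniform(-jitter_max, jitter_max, n)).astype(np.int64)
    labels = np.concatenate([[cls] * k for cls, k in counts.items() if k > 0])
    labels = rng.permutation(labels)

    w = solve_center_weight(cfg)

    rows, truth_rows = [], []
    for i, (mid, cls) in enumerate(zip(mids, labels)):
        pid = f"peak_{i + 1:04d}"
        rows.append(
            {
                "id": pid,
                "chrom": cfg.chrom,
                "start": int(mid - cfg.peak_halfwidth),
                "end": int(mid + cfg.peak_halfwidth),
            }
        )
        truth_rows.append(
            {
                "peak_id": pid,
                "class": cls,
                "midpoint": int(mid),
                "planted_slide_bp": cfg.slide_bp if cls == "G3" else 0,
                "planted_eviction_fraction": (
                    cfg.eviction_fraction if cls in ("G1", "G4") else np.nan
                ),
                "tf_enrichment": cfg.tf_enrichment
                * (cfg.g3_tf_multiplier if cls == "G3" else 1.0),
                "open_control": cls in ("G2", "G4"),
                "open_treated": cls in ("G1", "G2"),
                "thermal_destabilization_factor": (
                    cfg.thermal_destabilization_factor if cls == "G3" else 1.0
                ),
                "seed": cfg.seed,
            }
        )
    peaks = PeakSet(pd.DataFrame(rows))
    truth = pd.DataFrame(truth_rows)

    # TSS: a fraction of peaks get a proximal TSS; every fifth peak also
    # contributes a distal TSS halfway to its neighbour
    proximal = rng.random(n) < cfg.tss_proximal_fraction
    tss_rows = []
    for i, (mid, prox) in enumerate(zip(mids, proximal)):
        if prox:
            tss_rows.append({"chrom": cfg.chrom, "pos": int(mid + rng.integers(-800, 801))})
        if i % 5 == 0:
            tss_rows.append({"chrom": cfg.chrom, "pos": int(mid + spacing // 2)})
    tss = pd.DataFrame(tss_rows).drop_duplicates().reset_index(drop=True)
    return Layout(cfg, peaks, truth, tss, w)


# ---------------------------------------------------------------------------
# analytic landscapes
# ---------------------------------------------------------------------------

_TEMPLATE_HALF = 1_200  # template grid half-width (holds tails and slid arrays)


def _template_grid() -> np.ndarray:
    return np.arange(-_TEMPLATE_HALF, _TEMPLATE_HALF + 1)


def _gaussians(grid, centers, weights, sd):
    out = np.zeros(len(grid))
    for c, w in zip(centers, weights):
        out += w * stats.norm.pdf(grid, loc=c, scale=sd)
    return out


def dyad_template(cfg: SimulationConfig, cls: str, condition: str, center_weight: float) -> np.ndarray:
    """Expected dyad density (mass units: one nucleosome = 1) around a
    planted peak of the given class/condition, on the ±1.2 kb grid."""
    grid = _template_grid()
    sp, nk = cfg.nucleosome_spacing, cfg.n_flank_nucleosomes
    phased = [k * sp for k in range(-nk, nk + 1) if k != 0]

    def smear(total_mass):
        # unphased flank occupancy: same mass spread uniformly over the
        # flank regions the phased dyads would occupy
        lo, hi = sp - sp // 2, nk * sp + sp // 2
        dens = np.zeros(len(grid))
        per_bp = (total_mass / 2) / (hi - lo)
        dens[(grid >= lo) & (grid <= hi)] = per_bp
        dens[(grid <= -lo) & (grid >= -hi)] = per_bp
        return dens

    occupied_center = _gaussians(grid, [0], [1.0], cfg.dyad_sd)
    phased_flanks = _gaussians(grid, phased, np.ones(len(phased)), cfg.dyad_sd)

    if cls == "G1":
        if condition == "control":
            return occupied_center + smear(2 * nk)
        return center_weight * occupied_center + phased_flanks
    if cls == "G2":
        return phased_flanks
    if cls == "G3":
        shift = cfg.slide_bp if condition == "treated" else 0
        dyads = [k * sp + shift for k in range(-nk, nk + 1)]
        return _gaussians(grid, dyads, np.ones(len(dyads)), cfg.dyad_sd)
    if cls == "G4":
        if condition == "control":
            return center_weight * occupied_center + phased_flanks
        return occupied_center + smear(2 * nk)
    raise ValidationError(f"unknown class {cls!r}")


def _coverage_kernel(cfg: SimulationConfig) -> np.ndarray:
    """P(a fragment with this midpoint covers a base at distance d):
    boxcar of the nucleosomal footprint softened by length variation."""
    d = np.arange(-(cfg.footprint // 2 + 40), cfg.footprint // 2 + 41)
    half_sd = max(cfg.fragment_length_sd / 2.0, 1e-6)
    return stats.norm.cdf((cfg.footprint / 2.0 - np.abs(d)) / half_sd)


def _total_dyad_mass(cfg: SimulationConfig, center_weight: float) -> float:
    counts = cfg.class_counts()
    total = 0.0
    for cls, k in counts.items():
        if k == 0:
            continue
        # per-window mass is condition-symmetric by construction
        total += k * dyad_template(cfg, cls, "control", center_weight).sum()
    return total


def expected_mnase_profile(
    cfg: SimulationConfig,
    cls: str,
    condition: str,
    center_weight: float,
    params: Parameters | None = None,
) -> MetageneProfile:
    """Noiseless expectation of the per-locus-normalized, smoothed MNase
    coverage metagene for one class/condition — the generative oracle the
    eviction inversion and the simulator tests are checked against."""
    params = params or Parameters()
    grid = _template_grid()
    dens = dyad_template(cfg, cls, condition, center_weight)
    coverage = np.convolve(dens, _coverage_kernel(cfg), mode="same")
    # uniform background in dyad-mass units per bp
    total_mass = _total_dyad_mass(cfg, center_weight)
    beta = (
        cfg.mnase_background / (1 - cfg.mnase_background) * total_mass / cfg.genome_length
    )
    coverage = coverage + beta * cfg.footprint
    # restrict to the ±flank window and apply the estimator's pipeline
    half = params.flank_window_bp
    window = coverage[(grid >= -half) & (grid < half)]
    bin_bp = params.metagene_bin_bp
    binned = window.reshape(-1, bin_bp).mean(axis=1)
    normalized = binned / (binned.sum() * bin_bp)
    smoothed = moving_average(normalized, params.moving_average_n)
    return MetageneProfile(bin_offsets(2 * half, bin_bp), smoothed, 1)


def solve_center_weight(cfg: SimulationConfig) -> float:
    """Solve the evicted-center nucleosome weight so that the planted
    eviction fraction equals the noiseless central-density drop."""
    f = cfg.eviction_fraction
    if not (0 <= f < 1):
        raise ValidationError("eviction fraction must be in [0, 1)")
    params = Parameters()
    halfwidth = 90

    def central(profile):
        sel = np.abs(profile.offsets) <= halfwidth
        return profile.mean_density[sel].mean()

    def g(w):
        occupied = expected_mnase_profile(cfg, "G1", "control", w, params)
        evicted = expected_mnase_profile(cfg, "G1", "treated", w, params)
        return central(evicted) / central(occupied) - (1 - f)

    if f == 0:
        return 1.0
    return float(optimize.brentq(g, 0.0, 1.0, xtol=1e-6))


def _occupancy_landscape(layout: Layout, condition: str) -> np.ndarray:
    cfg = layout.config
    occ = np.zeros(cfg.genome_length)
    grid_len = 2 * _TEMPLATE_HALF + 1
    templates = {
        cls: dyad_template(cfg, cls, condition, layout.center_weight) for cls in CLASSES
    }
    for row in layout.truth.to_dict("records"):
        lo = row["midpoint"] - _TEMPLATE_HALF
        occ[lo: lo + grid_len] += templates[row["class"]]
    return occ


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def _sample_positions(rate: np.ndarray, n: int, rng) -> np.ndarray:
    cdf = np.cumsum(rate)
    return np.searchsorted(cdf, rng.random(n) * cdf[-1], side="right").astype(np.int64)


def simulate_mnase(
    layout: Layout,
    condition: str,
    depth: int | None = None,
    rng: np.random.Generator | None = None,
    background: bool = True,
) -> FragmentSet:
    """Mononucleosome-sized fragments sampled from the occupancy landscape
    plus a uniform background; total count is Poisson at the depth."""
    cfg = layout.config
    depth = cfg.depth_mnase if depth is None else int(depth)
    if depth <= 0:
        raise ValidationError("depth must be > 0")
    rng = rng or _rng(cfg.seed, ("MNASE", condition))
    occ = _occupancy_landscape(layout, condition)
    bgf = cfg.mnase_background if background else 0.0
    occ_sum = occ.sum()
    if occ_sum > 0:
        rate = (1 - bgf) * occ / occ_sum + bgf / cfg.genome_length
    else:
        rate = np.full(cfg.genome_length, 1.0 / cfg.genome_length)
    n = rng.poisson(depth)
    mids = _sample_positions(rate, n, rng)
    lengths = np.clip(
        np.round(rng.normal(cfg.footprint, cfg.fragment_length_sd, n)), 100, 200
    ).astype(np.int64)
    starts = np.clip(mids - lengths // 2, 0, cfg.genome_length - 1)
    ends = np.minimum(starts + lengths, cfg.genome_length)
    df = pd.DataFrame(
        {"chrom": cfg.chrom, "start": starts, "end": ends, "strand": "."}
    )
    return FragmentSet("MNASE", condition, df, is_paired=True)


def accessibility_landscape(layout: Layout, condition: str) -> np.ndarray:
    """Cut-site rate: uniform floor of 1 everywhere; open windows add
    (fold - 1) x inverse-occupancy shape, so the open-center rate is
    `accessibility_fold` times background."""
    cfg = layout.config
    acc = np.ones(cfg.genome_length)
    grid = _template_grid()
    half = Parameters().flank_window_bp
    sel = (grid >= -half) & (grid < half)
    kernel = _coverage_kernel(cfg)
    shapes = {}
    for cls in CLASSES:
        cov = np.convolve(
            dyad_template(cfg, cls, condition, layout.center_weight), kernel, mode="same"
        )[sel]
        peak = cov.max()
        shapes[cls] = np.clip(1 - cov / peak, 0, 1) if peak > 0 else np.ones(sel.sum())
    open_col = "open_treated" if condition == "treated" else "open_control"
    for row in layout.truth.to_dict("records"):
        if not row[open_col]:
            continue
        lo = row["midpoint"] - half
        acc[lo: lo + 2 * half] += (cfg.accessibility_fold - 1.0) * shapes[row["class"]]
    return acc


def simulate_atac(
    layout: Layout,
    condition: str,
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> FragmentSet:
    """Single-end stranded reads whose 5' ends are pre-shifted -4/+5 so
    that Tn5 offset correction recovers the true cut sites."""
    cfg = layout.config
    depth = cfg.depth_atac if depth is None else int(depth)
    if depth <= 0:
        raise ValidationError("depth must be > 0")
    rng = rng or _rng(cfg.seed, ("ATAC", condition))
    rate = accessibility_landscape(layout, condition)
    n = rng.poisson(depth)
    cuts = _sample_positions(rate, n, rng)
    plus = rng.random(n) < 0.5
    L = cfg.genome_length
    rl = cfg.atac_read_length
    starts = np.where(plus, cuts - 4, cuts + 5 - rl)
    starts = np.clip(starts, 0, L - rl)
    ends = starts + rl
    df = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": starts,
            "end": ends,
            "strand": np.where(plus, "+", "-"),
        }
    )
    return FragmentSet("ATAC", condition, df, is_paired=False)


# per-class (control, treated) flank-nucleosome mark weights: enhancer
# marks gain at G1 with factor expression, are high throughout at G2,
# low at G3, and are lost at G4
_HISTONE_WEIGHTS = {
    "G1": (0.5, 2.0),
    "G2": (1.0, 1.3),
    "G3": (0.3, 0.35),
    "G4": (2.0, 0.5),
}


def _chip_rate(layout: Layout, factor: str, condition: str, thermal: str) -> np.ndarray:
    cfg = layout.config
    rate = np.zeros(cfg.genome_length)
    grid = _template_grid()
    sp = cfg.nucleosome_spacing
    if factor == "TF":
        shape = stats.norm.pdf(grid, 0, 60.0)
    elif factor in ("H3K4me1", "H3K27ac"):
        dyads = [k * sp for k in (-3, -2, -1, 1, 2, 3)]
        shape = _gaussians(grid, dyads, np.ones(6), 50.0) / 6.0
    elif factor == "cofactor":
        shape = stats.norm.pdf(grid, 0, 80.0)
    else:
        raise ValidationError(f"unknown ChIP factor {factor!r}")
    for row in layout.truth.to_dict("records"):
        cls = row["class"]
        if factor == "TF":
            if condition != "treated":
                continue  # the factor is absent in control cells
            w = row["tf_enrichment"]
            if thermal == "37C":
                w *= row["thermal_destabilization_factor"]
        elif factor == "cofactor":
            w = 2.0 if (cls == "G1" and condition == "treated") else 0.0
        else:
            w = _HISTONE_WEIGHTS[cls][1 if condition == "treated" else 0]
        if w <= 0:
            continue
        lo = row["midpoint"] - _TEMPLATE_HALF
        rate[lo: lo + len(grid)] += w * shape
    return rate


def simulate_chip(
    layout: Layout,
    factor: str,
    condition: str,
    thermal: str = "ice",
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> FragmentSet:
    """ChIP fragments around factor-specific anchors plus uniform background.

    TF reads center on peak midpoints with per-class enrichment (G3 is
    half of G1/G2 by default); at thermal='37C' the G3 enrichment is
    further multiplied by the destabilization factor. Histone-mark reads
    center on flanking nucleosomes with condition-dependent gains/losses;
    cofactor reads appear at G1 peaks in the treated condition only.
    """
    cfg = layout.config
    if factor not in CHIP_FACTORS:
        raise ValidationError(f"unknown ChIP factor {factor!r}")
    if thermal not in ("ice", "37C"):
        raise ValidationError("thermal must be 'ice' or '37C'")
    depth = cfg.depth_chip if depth is None else int(depth)
    if depth <= 0:
        raise ValidationError("depth must be > 0")
    if rng is None:
        stream = (factor, condition, thermal)
        rng = _rng(cfg.seed, stream if stream in _STREAMS else (factor, condition, "ice"))
    enriched = _chip_rate(layout, factor, condition, thermal)
    bgf = cfg.chip_background
    total = enriched.sum()
    if total > 0:
        rate = (1 - bgf) * enriched / total + bgf / cfg.genome_length
    else:
        rate = np.full(cfg.genome_length, 1.0 / cfg.genome_length)
    n = rng.poisson(depth)
    mids = _sample_positions(rate, n, rng)
    flen = cfg.chip_fragment_length
    starts = np.clip(mids - flen // 2, 0, cfg.genome_length - flen)
    ends = starts + flen
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    df = pd.DataFrame({"chrom": cfg.chrom, "start": starts, "end": ends, "strand": strands})
    return FragmentSet("CHIP", condition, df, is_paired=False)


# ---------------------------------------------------------------------------
# dataset on disk
# ---------------------------------------------------------------------------

def write_dataset(config: SimulationConfig, out_dir, force: bool = False) -> dict:
    """Generate the full default dataset and write it as plain-text files.

    Returns a manifest mapping logical names to paths. Refuses to write
    into a non-empty directory unless ``force`` is set.
    """
    from . import io as pio  # local import to avoid a cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise ValidationError(f"output directory {out} is not empty (use force)")

    layout = plant_layout(config)
    cfg = config
    genome = {cfg.chrom: cfg.genome_length}
    manifest = {}

    def save(name, writer, *args):
        path = out / name
        writer(*args, path)
        manifest[name] = str(path)

    save("chrom.sizes", pio.write_chrom_sizes, genome)
    save("peaks.bed", pio.write_peaks, layout.peaks)
    (out / "tss.bed").write_text(
        "".join(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\n" for r in layout.tss.itertuples())
    )
    manifest["tss.bed"] = str(out / "tss.bed")
    layout.truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    manifest["truth.tsv"] = str(out / "truth.tsv")

    for cond in ("control", "treated"):
        save(f"atac_{cond}.bed", pio.write_fragments, simulate_atac(layout, cond))
        save(f"mnase_{cond}.bedpe", pio.write_fragments, simulate_mnase(layout, cond))
        save(f"chip_tf_{cond}.bed", pio.write_fragments,
             simulate_chip(layout, "TF", cond, "ice"))
        for mark in ("H3K4me1", "H3K27ac"):
            save(f"chip_{mark.lower()}_{cond}.bed", pio.write_fragments,
                 simulate_chip(layout, mark, cond))
        save(f"chip_cofactor_{cond}.bed", pio.write_fragments,
             simulate_chip(layout, "cofactor", cond))
    save("chip_tf_treated_37C.bed", pio.write_fragments,
         simulate_chip(layout, "TF", "treated", "37C"))

    meta = cfg.to_dict()
    meta["files"] = {k: Path(v).name for k, v in manifest.items()}
    with open(out / "dataset.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    manifest["dataset.yaml"] = str(out / "dataset.yaml")
    return manifest
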