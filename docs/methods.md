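# Methods

This note documents the models, estimators and numerical choices behind
`pioneerclass`, what the synthetic-data generator does and does not
emulate, and the limitations a user should know about.

## Coordinate and data model

All coordinates are 0-based half-open (BED convention). Fragments are
carried as array-backed tables (chrom, start, end, strand); replicates are
merged by concatenation before analysis — no replicate-aware dispersion
estimation is attempted, which is why the differential test takes a fixed
dispersion (below). Signal tracks store per-base values sparsely (sorted
position/value arrays per chromosome with cumulative sums), so windowed
counts are O(log n) and a 2 Mb synthetic genome, or windows of a real
genome, fit comfortably in memory; dense arrays are materialized only
inside profile windows.

## Preprocessing

* **Duplicate removal** is coordinate-identity collapse on
  (chrom, start, end, strand). It exists for real libraries with PCR
  duplicates; the pipeline leaves it off by default for simulated reads,
  where identical coordinates are genuine independent molecules
  (a miniature genome collides constantly, and removing collisions would
  distort counts in exactly the high-signal windows being measured).
* **Tn5 offset correction**: the transposase inserts as a dimer, so
  sequenced 5′ ends sit 4–5 bp off the insertion point. Plus-strand ends
  are shifted +4, minus-strand ends −5 (on the half-open end coordinate);
  paired fragments contribute both ends. Shifts falling outside the
  chromosome are clipped and tallied. Offsets are parameters for other
  transposases.
* **Paired-end conversion**: BEDPE mates are collapsed to one fragment
  spanning min(start)–max(end); interchromosomal pairs are skipped and
  counted.
* **Depth normalization** scales a track by target/total. The default
  target is 30 million (the convention for genome-scale libraries). For
  the 2 Mb synthetic genome the simulator recommends a genome-size-matched
  target, 30 M × L/3.1 Gb (= 19,355 for 2 Mb), written into
  `dataset.yaml` and picked up by the CLI: it keeps windowed counts on the
  same per-bp scale as a 30 M-read genome-wide library, which is the scale
  on which the 20-count open/closed cutoff is meaningful.

## Binding-site classification

Counts are collected in the midpoint ± 100 bp window in both conditions and
in the control midpoint ± 1 kb flank, from tracks normalized to a common
total.

The differential test is an exact conditional rate test. Conditional on the
window total N = x_a + x_b, under the null of equal per-base rates x_a
follows Binomial(N, π) with π = n_a/(n_a + n_b) (equal library totals give
π = ½). With dispersion φ > 0, each count is modelled NB(μ, φ)
(Var = μ + φμ²) and the conditional law is computed by enumerating
k = 0…N with weights NB(k; Nπ, φ)·NB(N−k; N(1−π), φ), normalized — for
equal libraries this is the negative-hypergeometric distribution. The
two-sided p-value doubles the smaller tail (observed point included),
capped at 1; x_a = x_b = 0 returns 1 (no evidence). Counts are rounded to
the nearest integer for the conditional test. The default φ = 0.1 is a
typical common dispersion for merged biological material and makes the
test conservative relative to the pure binomial; it is configurable, and
φ = 0 recovers the exact binomial test (verified against a brute-force
oracle to 1e-12 in the test suite).

FDR control is Benjamini–Hochberg (step-up, running minimum, input order
preserved). Class assignment: G1 if FDR < 0.1 and fold change > 2 upward,
G4 if downward; fold change is (x_t + 0.5)/(x_c + 0.5) on normalized
counts, thresholds strict so exact ties fall to the conserved classes.
Conserved peaks are G2 if the control ±1 kb flank count is ≥ 20, else G3.
The cutoff is applied to the flank window, reconciling the open/closed
intent (central 200 bp counts of pre-open sites can sit near the cutoff
while the flank separates cleanly). TSS annotation takes the minimum
midpoint-to-TSS distance (same chromosome preferred, global fallback);
≤ 1 kb is proximal. Peak-set overlap (for wild-type/mutant Venn counts)
uses ≥ 1 bp interval overlap.

## Profiling

Profile matrices bin the window [−w/2, +w/2) around each midpoint into
densities per bp (metagene: ±1 kb at 10 bp; heatmap: 10 kb at 100 bp —
window sizes are the analysis convention, bin sizes are this package's
choice). Heatmap rows are ordered within class blocks G1→G4 by decreasing
Gaussian-weighted (σ = 250 bp, configurable) ATAC signal in ±1 kb, ties by
peak id; "weighted signal" is not standardized anywhere, and the Gaussian
weight emphasizes midpoint accessibility.

MNase metagenes are per-locus normalized: each peak's binned density over
±1 kb is divided by that peak's window total, so a 10×-covered locus
contributes the same as a 1×-covered one; zero-signal peaks are dropped
and reported. Profiles use full-fragment coverage by default (paired reads
having been collapsed to single fragments); a fragment-midpoint (dyad
proxy) mode is available. Class averages are smoothed with a centered
moving average over N = 5 bins (truncated at edges).

Group comparisons use two-sided Mann–Whitney tests (scipy): exact
enumeration when both groups have n ≤ 8 and no cross-group ties, the
tie-corrected normal approximation otherwise; box statistics report n,
median, mean, and the 5th/95th percentiles.

## Nucleosome-dynamics estimators

All scores operate on the per-locus-normalized, smoothed class metagenes
(class level by default; a per-peak mode is sensible only at high depth).

* **Eviction** = (O_ctrl − O_treat)/O_ctrl, O = mean density over
  |offset| ≤ 90 bp (≈ one nucleosome footprint around the dyad;
  configurable). Positive = loss of central occupancy; invariant to common
  rescaling; undefined (NaN with warning) when the control center is empty.
* **Phasing** = max over lags 150–220 bp of the normalized autocorrelation
  of the mean-subtracted flank profile (|offset| > 90 bp). ≈ 1 for a clean
  array, 0 for flat; invariant to additive constants.
* **Sliding** = argmax over integer-bin lags of the cross-correlation of
  mean-subtracted profiles, ties toward 0, reported in bp. Two numerical
  choices matter for a periodic array with repeat a ≈ 190 bp: (i) the
  biased normalization (dot product divided by the full length, not the
  overlap) shrinks large-lag scores, and (ii) the lag search is bounded at
  ±90 bp < a/2, because for any true shift s the alias at s − a·sign(s)
  enters a wider window and is nearly as good (a ±150 bp bound recovers a
  planted 80 bp slide as −110 bp). Slides up to ±90 bp are therefore
  identifiable; larger slides are fundamentally confounded with the array
  period at metagene resolution.
* **Thermal stability** = per-peak (37 °C + 1)/(ice + 1) windowed ChIP
  signal ratio (±200 bp; pseudocount 1 guards empty windows), per-class
  medians, pairwise rank-sum tests. Because tracks are normalized to a
  common total, a genuine loss at one class appears as ratios slightly
  above 1 elsewhere; the between-class contrast is the readout, not the
  absolute ratio.

## The synthetic chromatin generator

One chromosome (default 2 Mb) carries 200 peaks per class on a jittered
grid (midpoints ≥ 5 kb from ends; spacing must exceed 2.1 kb so the ±1 kb
planted architectures never overlap — with the default 800 peaks the
spacing is ≈ 2.5 kb, so only the cosmetic 10 kb heatmap windows overlap,
in flat background). Nucleosomes are Gaussian dyad densities (sd 10 bp)
with a 190 bp repeat and 147 bp footprint:

* G1: control = occupied center + unphased flank occupancy (same mass,
  uniformly smeared); treated = weakened center + phased flanks.
* G2: nucleosome-depleted center, phased flanks, both conditions.
* G3: full array including the center, both conditions; the treated array
  is translated by the planted slide (default 50 bp).
* G4: the mirror of G1.

**Planted eviction is defined on the observable scale**: the fraction by
which per-locus-normalized central MNase density drops between conditions.
The generator solves the corresponding center-nucleosome weight by
root-finding on its own analytic expected profile (dyad density convolved
with the length-softened footprint kernel, plus uniform background, passed
through the same binning/normalization/smoothing as the estimator). This
matters because the naive parameterization ("remove fraction f of the
center nucleosome's mass") is not what any profile-based estimator can
measure: the 10% uniform background and the window renormalization (the
window total itself drops when a nucleosome leaves) bias the measured drop
downward by ≈ 0.08 at f = 0.8 independent of depth. With the
observable-scale definition the estimator recovers the planted value to
within sampling noise (±0.01 at default depth), and the analytic expected
profile doubles as an independent oracle in the tests.

MNase fragments (length 147 ± 10 bp) sample the occupancy landscape plus
10% uniform background, Poisson totals at the requested depth. ATAC cut
sites sample an accessibility landscape: a uniform floor of 1 everywhere
plus (fold − 1) × inverse-occupancy shape at open windows (open = G2 and
G4 in control; G1 and G2 treated). Reads are emitted single-end with the
5′ ends pre-shifted −4/+5 so the Tn5 correction path is exercised and
recovers the true cut sites. The accessibility fold defaults to 30: on a
miniature genome the mass budget (400 open windows over 2 Mb, normalized
to the genome-size-matched target) means open-window 200 bp counts
saturate near 20 however strong the signal; a fold of 30 — within the
30–100× per-bp enrichment range of strong accessible sites in real data —
yields ≈ 14 vs ≈ 0.7 counts, the count scale at which the conditional
test behaves as it does in genome-scale data. ChIP fragments (200 bp)
center on factor-specific anchors: TF at midpoints with per-class
enrichment (G3 half of G1/G2; thermal challenge multiplies G3 by the
destabilization factor, default 0.4), enhancer marks on flanking
nucleosomes with gain at G1/loss at G4 in the treated condition, cofactor
at treated G1 only; 15% uniform background.

All outputs are pure functions of (config, seed): every assay/condition
draws from its own numbered substream of one seed. The default dataset
writes as ≈ 195 MB of plain text in ≈ 40 s on one CPU.

**What the simulator does not emulate**: sequence content (no FASTQ, no
motifs), GC/mappability bias, fragment-length structure beyond a single
Gaussian, PCR duplicates, replicate batch effects, chromatin outside the
planted windows (background is uniform), and inter-peak heterogeneity
within a class (all peaks of a class share one architecture). Passing
tests therefore demonstrate estimator correctness and calibration under
the planted model, not robustness to the full messiness of real
libraries.

## Problem sizes used in validation

The test suite and the acceptance script run the default 800-peak / 2 Mb
configuration for classification (ATAC 1.5 M reads per condition), the
three slide settings {30, 50, 80} bp at default MNase depth (1 M), the
eviction recovery at 10× MNase depth, and the ChIP contrasts at 200 k
reads per library with 20 seeded null replicates for the enrichment null.
These sizes give stable rank statistics (n = 200 per class) while the
whole validation completes in a few minutes on one CPU.

## Known limitations

* The fixed-dispersion conditional test is a pragmatic stand-in for
  replicate-based dispersion estimation; with real replicated data a
  dedicated count-model package is preferable.
* Windowed counts are rounded to integers for the conditional test; at
  normalization targets far below the library depth this discards
  evidence, which is why the CLI matches the target to the genome scale.
* Class-level dynamics scores assume within-class homogeneity; per-peak
  scores need depths well above the defaults.
* The thermal-stability ratio is a reasonable summary of differential
  retention, not a calibrated measure of binding kinetics.
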