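# pioneerclass

Chromatin-state dissection of transcription-factor binding sites from
two-condition chromatin data.

Pioneer transcription factors can bind their motifs inside closed,
nucleosomal chromatin and convert those loci into accessible, enhancer-like
regions. Given a TF peak set and fragment-level sequencing data (ATAC-seq,
MNase-seq, ChIP-seq) for a control and a factor-expressing condition,
`pioneerclass`:

1. **classifies** every binding site by its accessibility response —
   * **G1**: closed → open (the pioneer class),
   * **G2**: pre-open, conserved,
   * **G3**: bound but closed in both conditions (nucleosome-embedded binding),
   * **G4**: open → closed;
2. **profiles** peak-centered signal (metagenes, read-density heatmap
   matrices ordered by weighted ATAC signal, per-locus-normalized MNase
   nucleosome profiles);
3. **quantifies nucleosome dynamics** — central-nucleosome eviction,
   flanking-array phasing, and array sliding — plus the thermal-stability
   contrast of ChIP retention that separates nucleosome-embedded binding;
4. **simulates** synthetic chromatin with planted G1–G4 architectures and a
   ground-truth table, so the whole pipeline is testable without external
   downloads.

It is aimed at computational epigenomicists studying de novo enhancer
establishment, and at anyone who needs a self-contained, tested reference
implementation of this class of analysis.

## The statistics at the core

**Differential accessibility.** ATAC fragments are reduced to Tn5 cut sites
(5′ ends shifted +4 bp on the plus strand, −5 bp on the minus strand), piled
up per base, and depth-normalized. With both libraries scaled to a common
total, counts in the 200 bp window on the peak midpoint are compared by an
exact conditional rate test: given the window total *N* = *x*<sub>a</sub> +
*x*<sub>b</sub>, under the null *x*<sub>a</sub> ~ Binomial(*N*,
*n*<sub>a</sub>/(*n*<sub>a</sub>+*n*<sub>b</sub>)) (dispersion 0), or an
overdispersed negative-binomial conditional law obtained by enumeration
(dispersion φ > 0, default 0.1; counts NB with Var = μ + φμ²). The two-sided
p-value doubles the smaller tail; Benjamini–Hochberg controls the FDR.
A peak is differential at FDR < 0.1 and fold change > 2 (pseudocount 0.5 per
side); conserved peaks are sub-split at 20 normalized counts in the control
±1 kb flank.

**Nucleosome dynamics.** MNase profiles are per-locus normalized (each
peak's ±1 kb window divided by its own total), averaged per class, and
smoothed (moving average, N = 5 bins). Then

* eviction = (O<sub>ctrl</sub> − O<sub>treat</sub>)/O<sub>ctrl</sub>, with O
  the mean density over |offset| ≤ 90 bp;
* phasing = maximal normalized autocorrelation of the mean-subtracted flank
  profile over lags of 150–220 bp;
* sliding = argmax-lag of the biased cross-correlation between conditions
  (bounded at ±90 bp, under half the 190 bp nucleosome repeat, so the
  one-spacing alias of a periodic array cannot win);
* thermal stability = per-peak (37 °C + 1)/(ice + 1) ChIP signal ratio over
  ±200 bp, compared across classes by two-sided Mann–Whitney tests.

## Worked example

Simulate a planted dataset and run the pipeline (about 30 s):

```sh
pioneerclass simulate --seed 42 -o ds --n-peaks-per-class 50 \
    --genome-length 600000 --depth-atac 450000 --depth-mnase 300000 \
    --depth-chip 60000
pioneerclass classify --peaks ds/peaks.bed \
    --atac-control ds/atac_control.bed --atac-treated ds/atac_treated.bed \
    --chrom-sizes ds/chrom.sizes --tss ds/tss.bed -o run
pioneerclass dynamics --classification run/classification.tsv \
    --chrom-sizes ds/chrom.sizes \
    --mnase-control ds/mnase_control.bedpe --mnase-treated ds/mnase_treated.bedpe \
    --chip-ice ds/chip_tf_treated.bed --chip-37c ds/chip_tf_treated_37C.bed \
    -o run
```

`classify` logs the class partition (here all 200 planted peaks recover
their class):

```
INFO pioneerclass: G1: 50 peaks (25.00%)
INFO pioneerclass: G2: 50 peaks (25.00%)
INFO pioneerclass: G3: 50 peaks (25.00%)
INFO pioneerclass: G4: 50 peaks (25.00%)
```

`run/dynamics.tsv` quantifies the planted nucleosome behaviour per class:

```
class  eviction_score  phasing_score_ctrl  phasing_score_treat  slide_bp
G1     0.798281        0.416453            0.997296             -90
G2     -0.0525581      0.996897            0.995822             0
G3     0.0634778       0.998486            0.997698             50
G4     -4.11033        0.996983            0.438028             90
```

Reading this: the pioneer class G1 loses ~0.80 of its central nucleosome
density (the planted eviction fraction was 0.8) while its flanks gain a
phased array (phasing 0.42 → 0.997); the nucleosome-embedded class G3 shows
no eviction (0.06) but its intact array slid by the planted 50 bp; G4 is the
mirror of G1 (its negative score is a central-density gain). The slide
estimates for G1/G4 are incidental — the architecture changes rather than
translates there, so only the G3 value is meaningful.

`run/stability.tsv` shows thermal challenge halving ChIP retention only at
the nucleosome-embedded class (G3 median ratio 0.47 vs ≈ 1.09 elsewhere),
and `run/classification.tsv` carries the per-peak statistics
(counts, log2FC, p, FDR, class, TSS distance/label). `pioneerclass profile`
adds metagene TSVs and the ordered heatmap matrix; `pioneerclass report`
summarizes a run directory (optionally with PNG plots).

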