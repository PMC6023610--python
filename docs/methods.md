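# Methods

## Scope and model

`talegrn` models two-stage genomic occupancy of TALE transcription
factors and its chromatin and expression context. The analysis operates
on five layers:

1. **Peaks.** ChIP-seq peaks are 0-based half-open intervals with an
   absolute summit and a fold enrichment (FE) over input. All comparisons
   between peaks are summit-to-summit and all thresholds are inclusive:
   the default enrichment filter keeps FE ≥ 10, two peaks colocalize when
   their summits are ≤ 50 bp apart, and a late peak is "late-only" when no
   early summit lies within 50 bp. Subtraction is performed against the
   *unfiltered* early calls so that a site is never classified late-only
   merely because its early peak fell below the FE cutoff. Nearest-distance
   queries use sorted summit arrays with binary search; the O(n·m)
   brute-force scan exists only as the test oracle.

2. **Motifs.** Motifs are IUPAC consensus strings scanned as regular
   expressions on both strands, with matches reported in forward
   coordinates and overlapping matches all retained. Presence is
   sequence-scoped and exclusion-aware: HEXA (`TGACAG`) is a substring of
   DECA (`TGATTGACAG`), so HEXA is counted only in sequences containing no
   DECA match anywhere. Exclusion conditions on the whole sequence, not on
   positional overlap, because a 200 bp summit window is the natural unit
   at which "this site uses the dimeric motif" is decided. Prevalence is
   the percent of 200 bp summit windows containing a motif. Enrichment
   between two peak populations is a two-sided Fisher's exact test on the
   presence/absence 2×2 table (odds ratio with Haldane +0.5 correction when
   a cell is zero). Motif spacing is the per-sequence minimum
   center-to-center distance among sequences containing both motifs;
   centers are defined at `position + length/2` so the statistic is
   symmetric for odd and even motif lengths.

3. **Signal.** Coverage is run-length bedGraph; uncovered bases are zero.
   A signal matrix holds, per peak, the coverage-weighted mean signal in
   25 bp bins across `[summit − flank, summit + flank)` (flank 1000 or
   2000 bp). Bin values are means rather than sums so the quantity is
   invariant to bin width; bases beyond a chromosome end contribute zero
   and the row is flagged rather than dropped, preserving the row order
   the classifier depends on. Temporal change is the cellwise
   `log2((t2 + 1) / (t1 + 1))`; the pseudocount of 1 keeps zero-coverage
   bins finite at the scale of these tracks.

4. **Chromatin classes.** Classification is two-level k-means (k = 4,
   k-means++ with 10 restarts, fixed seed, Euclidean distance on raw
   unscaled bins — standardization would erase the marked/unmarked
   contrast the labels encode). Level 1 clusters the H3K4me1 matrix;
   clusters whose mean signal is below 0.25× the top cluster's mean are
   non-MPAD, and if no cluster falls below that cutoff the single
   lowest-mean cluster is non-MPAD, so the 3-marked/1-unmarked topology is
   reproduced on any input. Level 2 clusters MPADs on the
   column-concatenated H3K27ac and H3K27me3 matrices jointly and orders
   clusters Class 1→4 by descending mean H3K27ac, breaking ties by
   ascending H3K27me3. Final labels depend only on cluster statistics,
   never on arbitrary cluster indices.

5. **Genes, expression, qPCR.** A gene is associated with a peak when any
   TSS lies within 5 or 30 kb (inclusive) of the peak-interval midpoint.
   DE tables are consumed, not fitted: a gene passes at padj ≤ 0.01 and
   linear fold-change magnitude ≥ 1.5. Class-wise expression compares
   per-gene `log2(mean TPM + 1)` (or the log2 ratio of condition means)
   across classes with Kruskal–Wallis followed by Dunn's rank-based
   post-hoc test (tie-corrected z statistics, Bonferroni-adjusted); Dunn's
   test is implemented in `talegrn.genes.dunn_posthoc` since no installed
   dependency provides it. Enrichment of a gene list near peaks is a
   seeded permutation test: the observed overlap with the peak-associated
   set is compared against `n_perm` uniform draws of equal size from the
   full annotation, with `p = (1 + #{null ≥ obs}) / (1 + n_perm)`. qPCR
   quantities assume perfect doubling per cycle
   (`0.5^Ct_gene / 0.5^Ct_ref`); group comparisons use a two-sided
   equal-variance Student t-test on replicate ratios with SEM from the
   (n−1) sample standard deviation, and replicates are normalized to their
   matched reference before condition means are divided.

## Synthetic data: what it emulates and what it does not

The generator writes a complete dataset whose ground truth is exact by
construction. Background sequence is i.i.d. uniform A/C/G/T — the
simplest null for motif scanning. Each peak's summit region (±115 bp) is
re-sampled until the central 200 bp window contains *exactly* the planned
motif content: chance DECA/HEXA/PBX:HOX/CCAAT matches are scrubbed out
and planted motifs are verified after embedding, so the emitted truth
table agrees with regex scanning of the emitted FASTA at every peak.
Short motifs such as CCAAT would otherwise appear by chance in roughly a
third of 200 bp windows and swamp the planted rates.

Defaults encode the emulated study conditions: 60% of early peaks remain
occupied late (at identical summits); 58% of late-only peaks are placed
300 bp–39.7 kb from a random early summit and the rest ≥ 45 kb from all
of them; DECA is embedded in 75% of early and 7% of late-only windows,
HEXA (inflated among DECA-free windows so the exclusion-aware marginal
hits the target) in 11% and 44%; CCAAT accompanies every planted DECA at
a center-to-center spacing drawn from N(20 bp, 4 bp) truncated to
[12, 60]; the Pbx:Hox site is offset ~N(10 bp, 3 bp) from the summit and
its late-only embedding rate is solved at generation time so the full
late peak set (retained + late-only) hits the configured 24% marginal.
25% of early peaks are marked (Classes 1–4, 6.25% each); tracks are
per-class Gaussian bumps (σ = 200 bp) at the summit with lognormal
amplitude variation and truncated-Gaussian noise, floored at zero — this
yields the ranked-heatmap structure without read-level simulation.
Expression is lognormal around class baselines; the knockdown condition
multiplies Class-4-linked gene means by 0.4, and the DE table is derived
from those true means rather than a fitted model.

What the generator does **not** emulate: real genome composition (GC
content, repeats, assembly gaps), mappability bias, read-level noise,
peak-width variation driven by fragment size, correlated histone-mark
backgrounds, or overdispersed count-based expression. Passing round-trip
tests therefore demonstrate that the *algorithms* recover planted
structure under realistic sampling noise — not that the pipeline is
robust to every artifact of real sequencing data.

## Numerical and design choices

- **Geometry.** Chromosomes are named `chrS1..chrSn` (equal length,
  default 3 Mb × 4) to avoid accidental dependence on real assemblies.
  Early peaks occupy the first 45% of each chromosome on a jittered grid
  with ≥ 600 bp gaps so scrubbed regions never overlap; distal late-only
  peaks live beyond a 45 kb buffer so their nearest-early distance is
  provably > 40 kb. Peak widths (400 bp) are free parameters with no
  empirical target.
- **Determinism.** One `numpy` Generator seeded from the config drives
  every random choice; identical configs produce byte-identical files,
  and k-means and the permutation test take explicit seeds.
- **Degenerate inputs.** An all-zero H3K4me1 matrix maps every peak to
  non-MPAD without invoking k-means; empty peak sets filter and fraction
  to empty/0; colocalization counts each peak once regardless of partner
  multiplicity; queries on chromosomes absent from the reference yield a
  missing distance that stays in the denominator of `fraction_within`
  (the reported percentages are over *all* query peaks).
- **Calibration tolerances.** The permutation p-value is superuniform by
  construction (discrete overlap statistic, `+1` correction), so the
  null-uniformity test bounds the Kolmogorov–Smirnov distance at 0.10 and
  additionally requires any deviation to be in the conservative
  direction; Kruskal–Wallis type-I error is required to sit within
  5% ± 2 points over 1000 null simulations.
- **Problem sizes.** Round-trip checks run at 5000 peaks per stage for
  motif rates, 2000 for peak geometry and 4000 for chromatin classes —
  large enough that binomial noise (≈ ±0.7–1.1 points) is several times
  smaller than the ±3-point recovery tolerance, while keeping a full run
  in seconds.

## Known limitations

- AME-style rank-sum motif enrichment is replaced by Fisher's exact test
  on window presence/absence; the two agree on direction but not on
  p-value scale.
- The "enrichment above random genes" test is an explicit permutation
  test; correlation-based variants are not implemented.
- Joint k-means on concatenated H3K27ac/H3K27me3 is this package's
  definition of the Class 1–4 split; clustering on H3K27ac alone would
  give similar but not identical boundaries.
- bigWig and BAM inputs are out of scope: bedGraph and narrowPeak text
  formats are the interchange.
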