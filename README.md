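# talegrn

Stage-resolved analysis of TALE transcription-factor genomic occupancy.

TALE-family homeodomain proteins (Prep, Pbx, Meis) bind the genome
throughout early vertebrate embryogenesis, but the *mode* of binding
changes with developmental stage. At blastula stages Prep occupies a 10 bp
dimeric **DECA** motif (`TGATTGACAG`, adjacent Pbx and Prep half-sites)
with an NF-Y **CCAAT** box typically ~20 bp away; by segmentation stages a
large new population of sites appears that instead carries the 6 bp
monomeric **HEXA** motif (`TGACAG`) near **PBX:HOX** sites (`TGATTTAT`).
A quarter of TALE-occupied sites carry histone marks (MPADs — *Modified
Prep Associated Domains*), and these split into Classes 1–4 by decreasing
H3K27ac, with Class 4 marked by repressive H3K27me3 and enriched near
developmental genes that depend on TALE function.

`talegrn` implements this entire analysis as a tested, reusable library:

| module               | what it does |
|----------------------|--------------|
| `talegrn.peaks`      | peak model, FE ≥ 10 filtering, summit colocalization (≤ 50 bp), stage-only subtraction, nearest-distance statistics, 200 bp summit windows, random-coordinate baselines |
| `talegrn.motifs`     | IUPAC consensus scanning on both strands, sequence-scoped nested-motif exclusion (HEXA counted only in DECA-free sequences), prevalence, summit-offset profiles, Fisher enrichment between peak populations, motif–motif spacing |
| `talegrn.signal`     | bedGraph tracks, reference-point signal matrices (flank 1000/2000 bp, bin 25 bp), mean profiles, log2 signal change, average score profiles |
| `talegrn.classify`   | k-means (k = 4) chromatin-state labeling: MPAD vs non-MPAD on H3K4me1, then Class 1–4 on joint H3K27ac/H3K27me3 |
| `talegrn.genes`      | TSS-window gene association (≤ 5/30 kb of peak center), DE filtering (padj ≤ 0.01, FC ≥ 1.5), Kruskal–Wallis + Dunn class-wise expression tests, permutation enrichment vs random gene sets |
| `talegrn.qpcr`       | Ct-based quantification (`0.5^Ct_gene / 0.5^Ct_ref`), replicate fold changes, unpaired t-tests |
| `talegrn.synthetic`  | generates a full toy dataset (genome, peaks, tracks, expression, Ct tables) with the structure above planted as ground truth |
| `talegrn.pipeline`   | orchestrates everything behind a config and a `talegrn` CLI, producing a `report.json` bundle |

## Worked example

```python
from talegrn.synthetic import SyntheticConfig, generate_dataset
from talegrn import io as tio, motifs
from talegrn.peaks import (filter_by_fold_enrichment, colocalize, stage_only,
                           distance_to_nearest, fraction_within)
import pyfaidx

cfg = SyntheticConfig(seed=7, n_early_peaks=1000, n_late_only_peaks=1000)
generate_dataset(cfg, "demo")

early = tio.read_narrowpeak("demo/peaks_early.narrowPeak")
late = tio.read_narrowpeak("demo/peaks_late.narrowPeak")
strong = filter_by_fold_enrichment(early, min_fe=10)
_, n_coloc, _ = colocalize(strong, late, max_summit_dist=50)
print(f"early peaks colocalizing with a late peak: {100 * n_coloc / len(strong):.1f}%")

late_only = stage_only(late, early, max_summit_dist=50)
d = distance_to_nearest(late_only, early)
print(f"late-only peaks within 40 kb of an early peak: {fraction_within(d, 40_000):.1f}%")

genome = pyfaidx.Fasta("demo/genome.fa")
print(motifs.prevalence(strong, genome).loc[["DECA", "HEXA", "NF-Y"]].round(1))
```

prints

```
early peaks colocalizing with a late peak: 58.3%
late-only peaks within 40 kb of an early peak: 58.8%
      count  total  percent
DECA    674    882     76.4
HEXA     96    882     10.9
NF-Y    674    882     76.4
```

The colocalization fraction recovers the generator's 60% retention rate
and the proximity fraction its 58% 40 kb-placement rate (both within
binomial sampling error at n = 1000); DECA prevalence in early summit
windows recovers the planted 75% rate, and HEXA — counted only in windows
with no DECA match — the planted 11%. NF-Y tracks DECA because the CCAAT
box is planted next to every DECA site.

The same analysis is available from the shell:

```bash
talegrn generate --seed 7 --out demo
talegrn run --seed 7 --out results_dir          # full pipeline + report.json
talegrn motifs --peaks demo/peaks_early.narrowPeak --genome demo/genome.fa \
        --out prevalence.tsv
```

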