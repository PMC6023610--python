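"""End-to-end orchestration of the TALE occupancy analysis.

Stage order: ingest (or generate) data -> fold-enrichment filter ->
colocalization / late-only subtraction / distance statistics -> motif
prevalence, enrichment and spacing -> signal matrices -> chromatin-state
classification -> gene association, expression tests and enrichment ->
qPCR summaries.  Every stage writes its own TSV next to a single
``report.json`` that aggregates the headline numbers; a fixed config (and
its seeds) reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from talegrn import classify, genes as genes_mod, io as tio, motifs, qpcr, signal
from talegrn.peaks import (
    colocalize,
    distance_to_nearest,
    filter_by_fold_enrichment,
    fraction_within,
    stage_only,
)
from talegrn.synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full pipeline run."""

    out_dir: str
    input_dir: str | None = None            # pre-existing dataset directory
    synthetic: SyntheticConfig | None = None  # or generate one
    min_fe: float = 10.0
    coloc_dist: int = 50
    near_threshold: int = 40_000
    gene_window: int = 30_000
    de_max_padj: float = 0.01
    de_min_fc: float = 1.5
    flank: int = 1000
    bin: int = 25
    k: int = 4
    seed: int = 0
    low_fraction: float = 0.25
    n_perm: int = 1000

    def validate(self) -> None:
        for name in ("min_fe", "coloc_dist", "near_threshold", "gene_window",
                     "de_max_padj", "de_min_fc", "flank", "bin", "k", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.input_dir is None and self.synthetic is None:
            raise ValueError("either input_dir or a synthetic config is required")


def run(config: PipelineConfig) -> dict:
    """Execute all stages and return the aggregated report dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {
        k: v for k, v in dataclasses.asdict(config).items() if k != "synthetic"
    }}

    stage = "ingest"
    try:
        if config.input_dir is None:
            data_dir = out / "data"
            manifest = generate_dataset(config.synthetic, data_dir)
            report["synthetic_summary"] = manifest["summary"]
        else:
            data_dir = Path(config.input_dir)
        early_all = tio.read_narrowpeak(data_dir / "peaks_early.narrowPeak", label="early")
        late = tio.read_narrowpeak(data_dir / "peaks_late.narrowPeak", label="late")
        fasta = pyfaidx.Fasta(str(data_dir / "genome.fa"))
        genome_map = {name: len(fasta[name]) for name in fasta.keys()}
        early_all.genome = genome_map
        late.genome = genome_map

        stage = "peaks"
        early = filter_by_fold_enrichment(early_all, config.min_fe)
        pairs, n_early_coloc, _ = colocalize(early, late, config.coloc_dist)
        late_only = stage_only(late, early_all, config.coloc_dist)
        dist = distance_to_nearest(late_only, early)
        pct_within = fraction_within(dist, config.near_threshold)
        report["peaks"] = {
            "n_early_unfiltered": len(early_all),
            "n_early": len(early),
            "n_late": len(late),
            "n_late_only": len(late_only),
            "pct_early_colocalized": 100.0 * n_early_coloc / max(len(early), 1),
            "pct_late_only_within_40kb": pct_within,
        }
        pd.DataFrame(pairs, columns=["early_id", "late_id"]).to_csv(
            out / "colocalized_pairs.tsv", sep="\t", index=False)
        pd.DataFrame({"peak_id": late_only.ids(), "nearest_early_bp": dist}).to_csv(
            out / "late_only_distances.tsv", sep="\t", index=False)

        stage = "motifs"
        registry = motifs.default_registry()
        prev_early = motifs.prevalence(early, fasta, registry)
        prev_late_only = motifs.prevalence(late_only, fasta, registry)
        prev_early.to_csv(out / "motif_prevalence_early.tsv", sep="\t")
        prev_late_only.to_csv(out / "motif_prevalence_late_only.tsv", sep="\t")
        win_early = motifs.window_sequences(early, fasta)
        win_late_only = motifs.window_sequences(late_only, fasta)
        deca_or, deca_p = motifs.enrichment_between(
            win_early, win_late_only, registry["DECA"], registry)
        hexa_or, hexa_p = motifs.enrichment_between(
            win_late_only, win_early, registry["HEXA"], registry)
        deca_hits, nfy_hits = [], []
        for sid, seq in win_early.items():
            deca_hits += motifs.scan(seq, registry["DECA"], sid)
            nfy_hits += motifs.scan(seq, registry["NF-Y"], sid)
        spacing = motifs.motif_spacing(
            deca_hits, nfy_hits, len(registry["DECA"]), len(registry["NF-Y"]))
        report["motifs"] = {
            "prevalence_early_pct": prev_early["percent"].to_dict(),
            "prevalence_late_only_pct": prev_late_only["percent"].to_dict(),
            "deca_enrichment_early_vs_late_only": {"odds_ratio": deca_or, "p": deca_p},
            "hexa_enrichment_late_only_vs_early": {"odds_ratio": hexa_or, "p": hexa_p},
            "nfy_deca_spacing_mean_bp": spacing["mean"],
            "nfy_deca_n_windows_with_both": spacing["n_with_both"],
        }

        stage = "signal"
        tracks = {}
        for mark, fname in (
            ("H3K4me1", "h3k4me1.bedGraph"),
            ("H3K27ac", "h3k27ac.bedGraph"),
            ("H3K27me3", "h3k27me3.bedGraph"),
            ("H3K27ac_late", "h3k27ac_late.bedGraph"),
        ):
            path = data_dir / fname
            if path.exists():
                tracks[mark] = signal.SignalTrack.from_bedgraph(path)
        matrices = {
            mark: signal.compute_matrix(t, early, flank=config.flank, bin=config.bin)
            for mark, t in tracks.items()
        }

        stage = "classify"
        assignment = None
        if {"H3K4me1", "H3K27ac", "H3K27me3"} <= set(matrices):
            assignment = classify.classify_peaks(
                matrices["H3K4me1"], matrices["H3K27ac"], matrices["H3K27me3"],
                k=config.k, seed=config.seed, low_fraction=config.low_fraction)
            assignment.to_tsv(out / "class_assignment.tsv")
            counts = assignment.counts()
            n_mpad = sum(v for lab, v in counts.items() if lab != classify.NON_MPAD)
            report["classes"] = {
                "counts": counts.to_dict(),
                "pct_mpad": 100.0 * n_mpad / max(len(early), 1),
            }
            if "H3K27ac_late" in matrices:
                _, row_change = signal.log2_change(
                    matrices["H3K27ac_late"], matrices["H3K27ac"])
                change = pd.Series(row_change, index=matrices["H3K27ac"].row_ids)
                per_class = {
                    lab: float(change.loc[assignment.peaks_with_label(lab)].mean())
                    for lab in classify.CLASS_LABELS
                    if assignment.peaks_with_label(lab)
                }
                report["classes"]["mean_log2_h3k27ac_change"] = per_class

        stage = "genes"
        gene_df = tio.read_tss_bed(data_dir / "tss.bed")
        gene_models = [
            genes_mod.GeneModel(r.gene_id, r.chrom, int(r.tss), r.strand)
            for r in gene_df.itertuples()
        ]
        links = genes_mod.associate(early, gene_models, window=config.gene_window)
        links.to_csv(out / "gene_links.tsv", sep="\t", index=False)
        report["genes"] = {"n_links": len(links),
                           "n_genes_linked": links["gene_id"].nunique()}
        de_path = data_dir / "de.tsv"
        expr_path = data_dir / "expression.tsv"
        if de_path.exists() and expr_path.exists() and assignment is not None:
            de = pd.read_csv(de_path, sep="\t")
            expression = pd.read_csv(expr_path, sep="\t")
            up, down = genes_mod.de_filter(de, config.de_max_padj, config.de_min_fc)
            ctrl_cols = [c for c in expression.columns if c.startswith("ctrl_")]
            kd_cols = [c for c in expression.columns if c.startswith("kd_")]
            summary = genes_mod.class_expression_summary(
                assignment, links, expression,
                sample_columns=ctrl_cols, ratio_columns=kd_cols)
            universe = gene_df["gene_id"].tolist()
            class4_peaks = set(assignment.peaks_with_label("Class4"))
            assoc4 = links.loc[links["peak_id"].isin(class4_peaks), "gene_id"].unique().tolist()
            observed, p_enrich = genes_mod.enrichment_vs_random(
                down, assoc4, universe, n_perm=config.n_perm, seed=config.seed)
            report["genes"].update({
                "n_de_up": len(up),
                "n_de_down": len(down),
                "kruskal": summary["kruskal"],
                "excluded_classes": summary["excluded_classes"],
                "class4_de_overlap": observed,
                "class4_de_enrichment_p": p_enrich,
            })
            if summary["dunn"] is not None:
                summary["dunn"].to_csv(out / "dunn_pvalues.tsv", sep="\t")

        stage = "qpcr"
        ct_path = data_dir / "ct.tsv"
        if ct_path.exists():
            ct = pd.read_csv(ct_path, sep="\t")
            qres = qpcr.analyze_ct_table(ct)
            qres.to_csv(out / "qpcr_results.tsv", sep="\t", index=False)
            report["qpcr"] = {
                "n_targets": len(qres),
                "n_significant": int(qres["significant"].sum()),
                "mean_fold_change": float(qres["fold_change"].mean()) if len(qres) else float("nan"),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return report
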