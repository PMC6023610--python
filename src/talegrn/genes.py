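"""Peak-to-gene association and class-wise expression analysis.

A gene is associated with a peak when any of its TSSs lies within 5 or
30 kb of the peak center (inclusive, both directions).  Downstream
summaries group genes by the chromatin class of their nearest associated
peak, compare log2 mean TPM (or TPM fold change) across classes with a
Kruskal-Wallis test followed by Dunn's post-hoc pairwise comparisons
(Bonferroni-corrected), and assess whether a gene list is enriched near
peaks relative to random gene sets by a seeded permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"


def associate(peaks, genes: list[GeneModel], window: int = 30_000) -> pd.DataFrame:
    """Peak-gene links: |peak center - TSS| <= window, same chromosome.

    Peak center is the interval midpoint (floor).  Many-to-many links are
    allowed.  Returns a DataFrame with columns peak_id, gene_id, distance
    (signed, TSS minus peak center).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_sorted = {
        c: sorted(gs, key=lambda g: g.tss) for c, gs in by_chrom.items()
    }
    tss_arrays = {
        c: np.array([g.tss for g in gs], dtype=np.int64) for c, gs in tss_sorted.items()
    }
    rows = []
    for p in peaks:
        arr = tss_arrays.get(p.chrom)
        if arr is None:
            continue
        center = p.center
        lo = int(np.searchsorted(arr, center - window, side="left"))
        hi = int(np.searchsorted(arr, center + window, side="right"))
        for g in tss_sorted[p.chrom][lo:hi]:
            rows.append((p.id, g.gene_id, g.tss - center))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])


def tss_distance_histogram(links: pd.DataFrame, bins: np.ndarray) -> np.ndarray:
    """Histogram of signed peak-center-to-TSS distances over given bin edges."""
    counts, _ = np.histogram(links["distance"].to_numpy(), bins=bins)
    return counts


def de_filter(
    records: pd.DataFrame, max_padj: float = 0.01, min_fc: float = 1.5
) -> tuple[list[str], list[str]]:
    """Split differentially expressed genes into up/down lists.

    A gene passes when padj <= ``max_padj`` and its linear fold-change
    magnitude is >= ``min_fc`` (both boundaries inclusive).  Fold changes
    below 1 are interpreted as down-regulation of magnitude 1/fc; an
    explicit ``direction`` column ('up'/'down') takes precedence.
    """
    if records.empty:
        return [], []
    fc = records["fold_change"].astype(float)
    magnitude = np.where(fc >= 1.0, fc, np.where(fc > 0, 1.0 / fc, np.inf))
    if "direction" in records.columns:
        direction = records["direction"].astype(str)
    else:
        direction = pd.Series(np.where(fc >= 1.0, "up", "down"), index=records.index)
    keep = (records["padj"].astype(float) <= max_padj) & (magnitude >= min_fc)
    up = records.loc[keep & (direction == "up"), "gene_id"].tolist()
    down = records.loc[keep & (direction == "down"), "gene_id"].tolist()
    return up, down


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with tie correction and Bonferroni.

    Ranks are computed over the pooled sample; for each pair the z statistic
    is the difference of mean ranks scaled by the tie-corrected null SD.
    Returns a symmetric DataFrame of Bonferroni-adjusted two-sided p-values.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term: sum over tied groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    offsets = np.cumsum([0] + [len(groups[g]) for g in names])
    mean_ranks = {
        g: ranks[offsets[i]: offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    m = len(names) * (len(names) - 1) // 2
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            na, nb = len(groups[a]), len(groups[b])
            sd = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))) * (1.0 / na + 1.0 / nb)
            )
            z = (mean_ranks[a] - mean_ranks[b]) / sd
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
            pmat.loc[a, b] = pmat.loc[b, a] = p
    return pmat


def class_expression_summary(
    assignment,
    links: pd.DataFrame,
    expression: pd.DataFrame,
    sample_columns: list[str],
    pseudocount: float = 1.0,
    ratio_columns: list[str] | None = None,
    min_genes: int = 2,
) -> dict:
    """Per-chromatin-class expression distributions with nonparametric tests.

    For each class, collects the genes linked to peaks of that class and
    computes per-gene log2(mean TPM over ``sample_columns`` + pseudocount);
    when ``ratio_columns`` is given the value is instead the log2 ratio of
    the two condition/timepoint means (fold-change semantics).  Classes with
    fewer than ``min_genes`` genes are excluded from testing and reported.
    Returns per-class value Series, the global Kruskal-Wallis result, and
    Dunn's Bonferroni-corrected pairwise p-values.
    """
    expr = expression.set_index("gene_id") if "gene_id" in expression.columns else expression
    missing = set(links["gene_id"]) - set(expr.index)
    if missing:
        raise ValueError(f"genes lacking expression: {sorted(missing)[:10]}")
    mean_a = expr[sample_columns].mean(axis=1)
    if ratio_columns is not None:
        mean_b = expr[ratio_columns].mean(axis=1)
        gene_value = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    else:
        gene_value = np.log2(mean_a + pseudocount)

    class_of_peak = assignment.labels
    per_class: dict[str, set] = {}
    for peak_id, gene_id in links[["peak_id", "gene_id"]].itertuples(index=False):
        label = class_of_peak.get(peak_id)
        if label is None or label == "nonMPAD":
            continue
        per_class.setdefault(label, set()).add(gene_id)
    values = {
        lab: gene_value.loc[sorted(gs)].to_numpy() for lab, gs in sorted(per_class.items())
    }
    excluded = [lab for lab, v in values.items() if len(v) < min_genes]
    tested = {lab: v for lab, v in values.items() if len(v) >= min_genes}
    result: dict = {
        "values": {lab: pd.Series(v) for lab, v in values.items()},
        "excluded_classes": excluded,
        "kruskal": None,
        "dunn": None,
    }
    if len(tested) >= 2:
        stat, p = stats.kruskal(*tested.values())
        result["kruskal"] = {"statistic": float(stat), "pvalue": float(p)}
        result["dunn"] = dunn_posthoc(tested)
    return result


def enrichment_vs_random(
    target_genes: list[str],
    associated_genes: list[str],
    universe: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[int, float]:
    """Permutation enrichment of a gene list within the peak-associated set.

    Observed statistic: |target ∩ associated|.  Null: overlaps of ``n_perm``
    uniform draws of |target| genes from the universe without replacement.
    Empirical p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    uni = sorted(set(universe))
    target = set(target_genes)
    assoc = set(associated_genes)
    if not target <= set(uni) or not assoc <= set(uni):
        raise ValueError("target and associated genes must be drawn from the universe")
    if len(target) > len(uni):
        raise ValueError("target larger than universe")
    observed = len(target & assoc)
    rng = np.random.default_rng(seed)
    is_assoc = np.array([g in assoc for g in uni])
    t = len(target)
    # vectorized draws without replacement: argpartition of uniform keys
    keys = rng.random((n_perm, len(uni)))
    idx = np.argpartition(keys, t - 1, axis=1)[:, :t] if t else np.empty((n_perm, 0), int)
    null = is_assoc[idx].sum(axis=1)
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return observed, p
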