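import numpy as np
import pandas as pd
import pytest
from scipy import stats

from talegrn.classify import ClassAssignment
from talegrn.genes import (
    GeneModel,
    associate,
    class_expression_summary,
    de_filter,
    dunn_posthoc,
    enrichment_vs_random,
)
from tests.conftest import random_peakset
from talegrn.peaks import Peak, PeakSet


def random_genes(rng, n, chroms=("chr1", "chr2"), chrom_len=100_000):
    return [
        GeneModel(f"g{i:04d}", chroms[int(rng.integers(0, len(chroms)))],
                  int(rng.integers(0, chrom_len)), "+")
        for i in range(n)
    ]


class TestAssociate:
    def test_inclusive_boundary(self):
        peak = Peak("chr1", 49_800, 50_200, 50_000, 20.0, "p")
        ps = PeakSet("x", [peak])
        genes = [GeneModel("g", "chr1", 80_000, "+")]
        links = associate(ps, genes, window=30_000)
        assert len(links) == 1 and links.iloc[0]["distance"] == 30_000
        assert associate(ps, [GeneModel("g", "chr1", 80_001, "+")], 30_000).empty

    def test_no_genes_on_chromosome(self):
        ps = PeakSet("x", [Peak("chr1", 0, 100, 50, 20.0, "p")])
        assert associate(ps, [GeneModel("g", "chr9", 50, "+")], 30_000).empty

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            ps = random_peakset(rng, 30)
            genes = random_genes(rng, 30)
            links = associate(ps, genes, window=20_000)
            expect = {
                (p.id, g.gene_id)
                for p in ps for g in genes
                if p.chrom == g.chrom and abs(p.center - g.tss) <= 20_000
            }
            assert set(map(tuple, links[["peak_id", "gene_id"]].values)) == expect

    def test_symmetry_of_distance_test(self, rng):
        ps = random_peakset(rng, 20)
        genes = random_genes(rng, 20)
        links = associate(ps, genes, window=15_000)
        centers = {p.id: p.center for p in ps}
        tss = {g.gene_id: g.tss for g in genes}
        for row in links.itertuples():
            assert abs(tss[row.gene_id] - centers[row.peak_id]) <= 15_000
            assert row.distance == tss[row.gene_id] - centers[row.peak_id]


class TestDeFilter:
    def test_inclusive_boundaries(self):
        df = pd.DataFrame({"gene_id": ["a"], "fold_change": [1.5],
                           "padj": [0.01], "direction": ["down"]})
        up, down = de_filter(df)
        assert down == ["a"] and up == []

    def test_empty_table(self):
        up, down = de_filter(pd.DataFrame(columns=["gene_id", "fold_change", "padj"]))
        assert up == [] and down == []

    def test_sub_unity_fold_change_is_down(self):
        df = pd.DataFrame({"gene_id": ["a", "b"], "fold_change": [0.4, 0.8],
                           "padj": [0.001, 0.001]})
        up, down = de_filter(df)
        assert down == ["a"] and up == []

    def test_matches_bruteforce_and_monotone(self, rng):
        n = 200
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "fold_change": rng.uniform(1.0, 4.0, n),
            "padj": rng.uniform(0, 0.05, n),
            "direction": rng.choice(["up", "down"], n),
        })
        up, down = de_filter(df, 0.01, 1.5)
        expect = df[(df.padj <= 0.01) & (df.fold_change >= 1.5)]
        assert len(up) + len(down) == len(expect)
        up2, down2 = de_filter(df, 0.02, 1.2)
        assert set(up) <= set(up2) and set(down) <= set(down2)


def make_summary_inputs(values_by_class, n_rep=1):
    """Build assignment/links/expression where each class has its own genes."""
    labels, links_rows, expr_rows = {}, [], []
    for lab, vals in values_by_class.items():
        for i, v in enumerate(vals):
            pid, gid = f"{lab}_p{i}", f"{lab}_g{i}"
            labels[pid] = lab
            links_rows.append((pid, gid, 0))
            expr_rows.append({"gene_id": gid,
                              **{f"s{r}": v for r in range(n_rep)}})
    assignment = ClassAssignment(labels=labels)
    links = pd.DataFrame(links_rows, columns=["peak_id", "gene_id", "distance"])
    expression = pd.DataFrame(expr_rows)
    return assignment, links, expression


class TestClassExpression:
    def test_single_gene_log2_arithmetic(self):
        assignment = ClassAssignment(labels={"p": "Class1", "q": "Class1"})
        links = pd.DataFrame({"peak_id": ["p", "q"], "gene_id": ["g", "h"],
                              "distance": [0, 0]})
        expression = pd.DataFrame({"gene_id": ["g", "h"],
                                   "s1": [3.0, 3.0], "s2": [5.0, 5.0]})
        res = class_expression_summary(assignment, links, expression,
                                       sample_columns=["s1", "s2"])
        # mean TPM 4, pseudocount 1 -> log2(5)
        assert res["values"]["Class1"].iloc[0] == pytest.approx(np.log2(5.0))

    def test_shifted_class_flagged_by_dunn(self, rng):
        vals = {f"Class{i}": rng.lognormal(3.0, 0.3, 60) for i in (1, 2, 3)}
        vals["Class4"] = rng.lognormal(3.0, 0.3, 60) * 4.0
        assignment, links, expression = make_summary_inputs(vals)
        res = class_expression_summary(assignment, links, expression,
                                       sample_columns=["s0"])
        assert res["kruskal"]["pvalue"] < 1e-6
        dunn = res["dunn"]
        for other in ("Class1", "Class2", "Class3"):
            assert dunn.loc["Class4", other] < 0.01

    def test_small_class_excluded_from_tests(self, rng):
        vals = {"Class1": rng.uniform(1, 5, 30), "Class2": rng.uniform(1, 5, 30),
                "Class3": [2.0]}
        assignment, links, expression = make_summary_inputs(vals)
        res = class_expression_summary(assignment, links, expression,
                                       sample_columns=["s0"])
        assert res["excluded_classes"] == ["Class3"]

    def test_missing_expression_rejected(self):
        assignment = ClassAssignment(labels={"p": "Class1"})
        links = pd.DataFrame({"peak_id": ["p"], "gene_id": ["g"], "distance": [0]})
        expression = pd.DataFrame({"gene_id": ["other"], "s1": [1.0]})
        with pytest.raises(ValueError):
            class_expression_summary(assignment, links, expression, ["s1"])

    def test_dunn_agrees_with_mannwhitney_direction(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(2, 1, 100)
        p = dunn_posthoc({"a": a, "b": b}).loc["a", "b"]
        assert p < 1e-6


class TestEnrichmentVsRandom:
    def test_associated_equals_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        obs, p = enrichment_vs_random(universe[:10], universe, universe,
                                      n_perm=200, seed=0)
        assert obs == 10 and p == 1.0

    def test_depletion_gives_large_p(self, rng):
        universe = [f"g{i}" for i in range(200)]
        associated = universe[:150]
        target = universe[180:]  # disjoint from associated
        _, p = enrichment_vs_random(target, associated, universe,
                                    n_perm=500, seed=1)
        assert p > 0.95

    def test_planted_enrichment_detected(self, rng):
        universe = [f"g{i}" for i in range(1000)]
        associated = universe[:100]
        target = universe[:40] + universe[900:910]  # 80% inside associated
        _, p = enrichment_vs_random(target, associated, universe,
                                    n_perm=1000, seed=2)
        assert p <= 0.01

    def test_p_bounds_and_reproducibility(self):
        universe = [f"g{i}" for i in range(100)]
        r1 = enrichment_vs_random(universe[:20], universe[:30], universe,
                                  n_perm=99, seed=3)
        r2 = enrichment_vs_random(universe[:20], universe[:30], universe,
                                  n_perm=99, seed=3)
        assert r1 == r2
        assert 1.0 / 100 <= r1[1] <= 1.0

    def test_target_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment_vs_random(["x"], ["a"], ["a", "b"], n_perm=10, seed=0)
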