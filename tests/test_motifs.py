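import math

import numpy as np
import pytest

from talegrn.motifs import (
    IUPAC,
    MotifHit,
    MotifSpec,
    default_registry,
    enrichment_between,
    iupac_regex,
    motif_spacing,
    presence,
    prevalence,
    reverse_complement,
    scan,
    summit_offset_profile,
)
from talegrn.peaks import Peak, PeakSet

REG = default_registry()
DECA, HEXA = REG["DECA"], REG["HEXA"]


def brute_scan(seq, consensus):
    """Exhaustive position-by-position IUPAC comparison on both strands."""
    def matches(s, cons):
        for a, c in zip(s, cons):
            opts = IUPAC[c] + ("N" if c == "N" else "")
            if a not in opts:
                return False
        return True

    hits = []
    for strand, cons in (("+", consensus), ("-", reverse_complement(consensus))):
        for i in range(len(seq) - len(cons) + 1):
            if matches(seq[i:i + len(cons)], cons):
                hits.append((i, strand))
    return sorted(hits, key=lambda h: (h[0], h[1] == "-"))


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestScan:
    def test_hexa_inside_deca_sequence(self):
        hits = scan("TGATTGACAG", HEXA)
        assert [(h.position, h.strand) for h in hits] == [(4, "+")]

    def test_reverse_complement_match(self):
        hits = scan("CTGTCA", HEXA)
        assert [(h.position, h.strand) for h in hits] == [(0, "-")]

    def test_wildcard_n(self):
        hits = scan("TGATCCATGG", REG["PBX:HOX-N"])
        assert (hits[0].position, hits[0].strand) == (0, "+")

    def test_invalid_iupac_code_named(self):
        with pytest.raises(ValueError, match="X"):
            MotifSpec("bad", "TGAXAG")

    def test_palindrome_double_hit(self):
        spec = MotifSpec("pal", "ACGT")
        hits = scan("ACGT", spec)
        assert [(h.position, h.strand) for h in hits] == [(0, "+"), (0, "-")]

    def test_subject_n_only_matches_motif_n(self):
        assert scan("TGNCAG", HEXA) == []
        assert len(scan("TGATNNAT", REG["PBX:HOX-N"])) >= 1

    @pytest.mark.parametrize("motif", ["DECA", "HEXA", "PBX:HOX-N", "SP/KLF"])
    def test_matches_exhaustive_oracle(self, motif, rng):
        spec = REG[motif]
        for _ in range(25):
            seq = random_seq(rng, 1000)
            got = [(h.position, h.strand) for h in scan(seq, spec)]
            assert got == brute_scan(seq, spec.consensus)

    def test_reverse_complement_invariance(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for name in REG:
            for _ in range(5):
                seq = random_seq(rng, 500)
                rc = seq.translate(comp)[::-1]
                assert len(scan(seq, REG[name])) == len(scan(rc, REG[name]))


class TestPresence:
    def test_deca_suppresses_hexa(self):
        assert presence("TGATTGACAG", DECA, REG) is True
        assert presence("TGATTGACAG", HEXA, REG) is False

    def test_hexa_alone(self):
        assert presence("AATGACAGAA", HEXA, REG) is True
        assert presence("AATGACAGAA", DECA, REG) is False

    def test_unresolvable_exclusion(self):
        orphan = MotifSpec("h", "TGACAG", excludes_when_present="missing")
        with pytest.raises(ValueError):
            presence("TGACAG", orphan, {"h": orphan})

    def test_matches_bruteforce_batch(self, rng):
        for _ in range(50):
            seq = random_seq(rng, 200)
            deca_raw = bool(brute_scan(seq, DECA.consensus))
            hexa_raw = bool(brute_scan(seq, HEXA.consensus))
            assert presence(seq, DECA, REG) == deca_raw
            assert presence(seq, HEXA, REG) == (hexa_raw and not deca_raw)


def _windows_as_peakset(seqs):
    """Wrap plain sequences as single-chromosome-per-peak genome + peaks."""
    genome = {f"c{i}": seqs[i] for i in range(len(seqs))}
    peaks = [
        Peak(f"c{i}", 0, len(s), len(s) // 2, 20.0, f"p{i}")
        for i, s in enumerate(seqs)
    ]
    return PeakSet("w", peaks, genome={c: len(s) for c, s in genome.items()}), genome


class TestPrevalence:
    def test_planted_deca_everywhere(self, rng):
        seqs = []
        for _ in range(20):
            s = random_seq(rng, 200)
            # avoid chance DECA elsewhere, then plant one at the center
            while brute_scan(s, DECA.consensus):
                s = random_seq(rng, 200)
            seqs.append(s[:95] + "TGATTGACAG" + s[105:])
        ps, genome = _windows_as_peakset(seqs)
        prev = prevalence(ps, genome, REG)
        assert prev.loc["DECA", "percent"] == 100.0
        assert prev.loc["HEXA", "percent"] == 0.0

    def test_background_rate_equals_bruteforce(self, rng):
        seqs = [random_seq(rng, 200) for _ in range(60)]
        ps, genome = _windows_as_peakset(seqs)
        prev = prevalence(ps, genome, REG)
        for name in REG:
            spec = REG[name]
            expect = 0
            for s in seqs:
                raw = bool(brute_scan(s, spec.consensus))
                if spec.excludes_when_present:
                    parent = REG[spec.excludes_when_present]
                    raw = raw and not brute_scan(s, parent.consensus)
                expect += raw
            assert prev.loc[name, "count"] == expect

    def test_peak_outside_genome_reported(self):
        ps = PeakSet("w", [Peak("cX", 0, 100, 50, 20.0, "bad")])
        with pytest.raises(ValueError, match="bad"):
            prevalence(ps, {"c0": "A" * 100}, REG)


class TestOffsetProfile:
    def test_centered_motif_mode_zero(self, rng):
        hits, offsets = [], {}
        for i in range(30):
            seq = random_seq(rng, 200)
            seq = seq[:97] + "TGACAG" + seq[103:]
            for h in scan(seq, HEXA, f"s{i}"):
                hits.append(h)
            offsets[f"s{i}"] = 100
        prof = summit_offset_profile(hits, offsets, len(HEXA), flank=100, bin=5)
        assert abs(prof["mode_offset"]) <= 5

    def test_uniform_plant_is_flat(self, rng):
        from scipy import stats
        hits, offsets = [], {}
        for i in range(3000):
            pos = int(rng.integers(0, 194))
            hits.append(MotifHit(f"s{i}", pos, "+", "HEXA"))
            offsets[f"s{i}"] = 100
        prof = summit_offset_profile(hits, offsets, 6, flank=90, bin=10)
        _, p = stats.chisquare(prof["counts"])
        assert p > 1e-4


class TestEnrichment:
    def test_null_case(self, rng):
        seqs = []
        for _ in range(40):
            s = random_seq(rng, 200)
            while brute_scan(s, DECA.consensus):
                s = random_seq(rng, 200)
            seqs.append(s)
        a = {f"a{i}": s[:95] + "TGATTGACAG" + s[105:] for i, s in enumerate(seqs[:20])}
        b = {f"b{i}": s[:95] + "TGATTGACAG" + s[105:] for i, s in enumerate(seqs[20:])}
        odds, p = enrichment_between(a, b, DECA, REG)
        assert p == pytest.approx(1.0)

    def test_extreme_table_matches_hypergeometric_tail(self, rng):
        plant = []
        empty = []
        while len(plant) < 20:
            s = random_seq(rng, 200)
            if not brute_scan(s, DECA.consensus):
                empty.append(s)
                plant.append(s[:95] + "TGATTGACAG" + s[105:])
        a = {f"a{i}": s for i, s in enumerate(plant)}
        b = {f"b{i}": s for i, s in enumerate(empty[:20])}
        _, p = enrichment_between(a, b, DECA, REG)
        # exact enumeration: P(all 20 positives land in one set) under the
        # null, doubled because the opposite extreme is equally probable
        expect = 2.0 / math.comb(40, 20)
        assert p == pytest.approx(expect, rel=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            enrichment_between({}, {"b": "ACGT"}, DECA, REG)


class TestSpacing:
    def test_planted_distance_recovered(self):
        # DECA center at 100.0, CCAAT at [113, 118) -> center 115.5
        seq = "A" * 95 + "TGATTGACAG" + "A" * 8 + "CCAAT" + "A" * 82
        d = scan(seq, DECA, "s0")
        n = scan(seq, REG["NF-Y"], "s0")
        res = motif_spacing(d, n, 10, 5)
        assert res["per_sequence"]["s0"] == pytest.approx(15.5)

    def test_sequences_missing_a_motif_are_excluded(self):
        d = scan("TGATTGACAG", DECA, "only_deca")
        res = motif_spacing(d, [], 10, 5)
        assert res["n_with_both"] == 0 and res["n_excluded"] == 1

    def test_matches_bruteforce_minimum(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 400)
            ha = scan(seq, HEXA, "s")
            hb = scan(seq, REG["NF-Y"], "s")
            if not ha or not hb:
                continue
            res = motif_spacing(ha, hb, 6, 5)
            expect = min(
                abs((a.position + 3) - (b.position + 2.5)) for a in ha for b in hb
            )
            assert res["per_sequence"]["s"] == pytest.approx(expect)
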