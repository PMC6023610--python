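"""IUPAC consensus motif scanning with nested-motif exclusion.

TALE binding sites come in nested flavors: the 10 bp dimeric DECA motif
(TGATTGACAG) literally contains the 6 bp monomeric HEXA motif (TGACAG), so
a naive substring count would call every DECA site HEXA-positive.  The
field's convention, which this module implements, is sequence-scoped
exclusion: HEXA is only counted in sequences that contain no DECA match at
all.  Scanning is regex-based on both strands, with matches reported in
forward coordinates; overlapping matches are all reported.

The default registry carries the motifs relevant to TALE biology:

========= ============ =============================================
name      consensus    note
========= ============ =============================================
DECA      TGATTGACAG   Pbx:Prep dimer site (adjacent half-sites)
HEXA      TGACAG       Prep/Meis monomer site; excluded by DECA
PBX:HOX   TGATTTAT     Pbx:Hox dimer site
PBX:HOX-N TGATNNAT     generic Pbx:Hox half-site pair
NF-Y      CCAAT        NF-Y pioneer-factor site, found near DECA
SP/KLF    CCMCRCCC     Sp/Klf family site (M = A/C, R = A/G)
AT-rich   ATRTTAA      unassigned AT-rich site
========= ============ =============================================
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(consensus: str) -> str:
    """Reverse complement of a DNA or IUPAC consensus string."""
    return consensus.translate(_COMPLEMENT)[::-1]


def iupac_regex(consensus: str) -> str:
    """Translate an IUPAC consensus into a regex character-class pattern.

    An N in the *subject* sequence matches only the motif code N (i.e. only
    a fully degenerate motif position tolerates an assembly gap).
    """
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in consensus {consensus!r}")
        opts = IUPAC[ch]
        if ch == "N":
            opts += "N"
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


@dataclass(frozen=True)
class MotifSpec:
    """A named IUPAC consensus, optionally suppressed by a parent motif.

    ``excludes_when_present`` names a motif whose raw presence in a sequence
    vetoes counting this motif there (the DECA-over-HEXA rule).
    """

    name: str
    consensus: str
    excludes_when_present: str | None = None

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name}: empty consensus")
        iupac_regex(self.consensus)  # validates alphabet

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    """A stranded match reported in forward coordinates of the subject."""

    sequence_id: str
    position: int
    strand: str
    motif: str

    def center(self, motif_length: int) -> float:
        return self.position + motif_length / 2.0


def default_registry() -> dict[str, MotifSpec]:
    specs = [
        MotifSpec("DECA", "TGATTGACAG"),
        MotifSpec("HEXA", "TGACAG", excludes_when_present="DECA"),
        MotifSpec("PBX:HOX", "TGATTTAT"),
        MotifSpec("PBX:HOX-N", "TGATNNAT"),
        MotifSpec("NF-Y", "CCAAT"),
        MotifSpec("SP/KLF", "CCMCRCCC"),
        MotifSpec("AT-rich", "ATRTTAA"),
    ]
    return {m.name: m for m in specs}


def _validate_registry(registry: dict[str, MotifSpec]) -> None:
    for name, spec in registry.items():
        parent = spec.excludes_when_present
        seen = {name}
        while parent is not None:
            if parent not in registry:
                raise ValueError(f"motif {name}: exclusion parent {parent!r} not in registry")
            if parent in seen:
                raise ValueError(f"motif {name}: exclusion cycle via {parent!r}")
            seen.add(parent)
            parent = registry[parent].excludes_when_present


def scan(sequence: str, motif: MotifSpec, sequence_id: str = "") -> list[MotifHit]:
    """All matches of the consensus on both strands, in forward coordinates.

    Overlapping matches are all reported; hits are ordered by position with
    '+' before '-' at equal positions.  A palindromic site therefore yields
    two hits at the same position.
    """
    seq = sequence.upper()
    hits = []
    for strand, cons in (("+", motif.consensus), ("-", reverse_complement(motif.consensus))):
        pat = re.compile("(?=" + iupac_regex(cons) + ")")
        for m in pat.finditer(seq):
            hits.append(MotifHit(sequence_id, m.start(), strand, motif.name))
    hits.sort(key=lambda h: (h.position, h.strand == "-"))
    return hits


def presence(
    sequence: str, motif: MotifSpec, registry: dict[str, MotifSpec] | None = None
) -> bool:
    """True iff the sequence has >= 1 hit and its exclusion parent has none.

    Exclusion is sequence-scoped: a single DECA match anywhere in the
    sequence suppresses HEXA for the whole sequence.
    """
    if motif.excludes_when_present is not None:
        if registry is None or motif.excludes_when_present not in registry:
            raise ValueError(
                f"motif {motif.name}: cannot resolve exclusion parent "
                f"{motif.excludes_when_present!r}"
            )
        if scan(sequence, registry[motif.excludes_when_present]):
            return False
    return bool(scan(sequence, motif))


def window_sequences(peaks, fasta, window: int = 200) -> dict[str, str]:
    """Extract summit-centered windows from an indexed FASTA.

    ``fasta`` is a mapping-style indexed genome (e.g. ``pyfaidx.Fasta``)
    supporting ``fasta[chrom][start:end]``.  Windows are clipped at
    chromosome ends.
    """
    from talegrn.peaks import summit_window

    out = {}
    missing = []
    for p in peaks:
        if p.chrom not in fasta:
            missing.append(p.id)
            continue
        chrom_len = len(fasta[p.chrom])
        s, e = summit_window(p, width=window, chrom_length=chrom_len)
        out[p.id] = str(fasta[p.chrom][s:e]).upper()
    if missing:
        raise ValueError(f"peaks outside genome: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    return out


def prevalence(
    peaks,
    fasta,
    registry: dict[str, MotifSpec] | None = None,
    window: int = 200,
) -> pd.DataFrame:
    """Percent of summit windows containing each motif, exclusions applied.

    Returns a DataFrame indexed by motif name with columns ``count``,
    ``total`` and ``percent``.
    """
    registry = registry if registry is not None else default_registry()
    _validate_registry(registry)
    seqs = window_sequences(peaks, fasta, window=window)
    total = len(seqs)
    rows = {}
    for name, spec in registry.items():
        count = sum(presence(s, spec, registry) for s in seqs.values())
        rows[name] = {
            "count": count,
            "total": total,
            "percent": 100.0 * count / total if total else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def presence_vector(
    sequences: dict[str, str], motif: MotifSpec, registry: dict[str, MotifSpec] | None = None
) -> pd.Series:
    registry = registry if registry is not None else default_registry()
    return pd.Series({sid: presence(s, motif, registry) for sid, s in sequences.items()})


def summit_offset_profile(
    hits: list[MotifHit],
    summit_offsets: dict[str, int],
    motif_length: int,
    flank: int = 100,
    bin: int = 5,
) -> dict:
    """Histogram of motif-center positions relative to the peak summit.

    ``summit_offsets`` maps sequence id to the summit position *within* the
    scanned sequence (window//2 for centered windows).  Returns bin edges,
    counts, and the mode and mean signed offset.
    """
    offsets = np.array(
        [h.center(motif_length) - summit_offsets[h.sequence_id] for h in hits
         if h.sequence_id in summit_offsets]
    )
    edges = np.arange(-flank, flank + bin, bin)
    counts, edges = np.histogram(offsets, bins=edges)
    if len(offsets):
        mode_bin = int(np.argmax(counts))
        mode = float((edges[mode_bin] + edges[mode_bin + 1]) / 2.0)
        mean = float(offsets.mean())
    else:
        mode = mean = float("nan")
    return {"edges": edges, "counts": counts, "mode_offset": mode,
            "mean_offset": mean, "offsets": offsets}


def enrichment_between(
    windows_a: dict[str, str],
    windows_b: dict[str, str],
    motif: MotifSpec,
    registry: dict[str, MotifSpec] | None = None,
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on presence/absence between two sets.

    Returns (odds ratio, p-value); the odds ratio uses the Haldane
    correction (+0.5 per cell) whenever a cell is zero.
    """
    if not windows_a or not windows_b:
        raise ValueError("both window sets must be nonempty")
    registry = registry if registry is not None else default_registry()
    pa = int(presence_vector(windows_a, motif, registry).sum())
    pb = int(presence_vector(windows_b, motif, registry).sum())
    table = [[pa, len(windows_a) - pa], [pb, len(windows_b) - pb]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b, c, d = pa, len(windows_a) - pa, pb, len(windows_b) - pb
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return float(odds), float(p)


def motif_spacing(
    hits_a: list[MotifHit],
    hits_b: list[MotifHit],
    length_a: int,
    length_b: int,
) -> dict:
    """Per-sequence minimum center-to-center distance between two motifs.

    Only sequences containing both motifs contribute; the number of
    sequences lacking one or both is reported as ``n_excluded``.
    """
    centers_a: dict[str, list[float]] = {}
    centers_b: dict[str, list[float]] = {}
    for h in hits_a:
        centers_a.setdefault(h.sequence_id, []).append(h.center(length_a))
    for h in hits_b:
        centers_b.setdefault(h.sequence_id, []).append(h.center(length_b))
    all_ids = set(centers_a) | set(centers_b)
    both = sorted(set(centers_a) & set(centers_b))
    per_seq = pd.Series(
        {
            sid: min(abs(ca - cb) for ca in centers_a[sid] for cb in centers_b[sid])
            for sid in both
        },
        dtype=float,
    )
    return {
        "per_sequence": per_seq,
        "mean": float(per_seq.mean()) if len(per_seq) else float("nan"),
        "n_with_both": len(per_seq),
        "n_excluded": len(all_ids) - len(per_seq),
    }
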