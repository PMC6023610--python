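"""Peak data model and summit-based interval operations.

ChIP-seq peaks are stored as 0-based half-open intervals with an absolute
summit coordinate (position of maximal enrichment) and a fold-enrichment
(FE) value over input.  All distance comparisons in this module are between
summits and all thresholds are inclusive: two peaks colocalize when their
summits are within 50 bp, and a peak passes the enrichment filter at
FE >= 10 (the defaults used throughout the pipeline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    """A single ChIP-seq peak.

    Coordinates are 0-based half-open; ``summit`` is absolute (not an
    offset from ``start``).
    """

    chrom: str
    start: int
    end: int
    summit: int
    fold_enrichment: float
    id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.id}: start must be < end")
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.id}: summit outside [start, end)")
        if self.fold_enrichment < 0:
            raise ValueError(f"peak {self.id}: negative fold enrichment")

    @property
    def center(self) -> int:
        """Interval midpoint (floor), used for TSS-window gene association."""
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """An ordered peak collection for one stage/condition.

    ``genome`` maps chromosome name to length and, when present, is used for
    bounds checking and for refusing colocalization across different
    assemblies.
    """

    label: str
    peaks: list[Peak] = field(default_factory=list)
    genome: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start))
        if self.genome is not None:
            for p in self.peaks:
                if p.chrom not in self.genome:
                    raise ValueError(f"peak {p.id}: chromosome {p.chrom} not in genome")
                if p.end > self.genome[p.chrom]:
                    raise ValueError(f"peak {p.id}: extends past end of {p.chrom}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    def summits_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted summit arrays keyed by chromosome (cached per call site)."""
        out: dict[str, list[int]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p.summit)
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}


def filter_by_fold_enrichment(peaks: PeakSet, min_fe: float = 10.0) -> PeakSet:
    """Retain peaks with fold enrichment >= ``min_fe`` (boundary inclusive)."""
    kept = [p for p in peaks if p.fold_enrichment >= min_fe]
    return PeakSet(label=peaks.label, peaks=kept, genome=peaks.genome)


def _check_same_genome(a: PeakSet, b: PeakSet) -> None:
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise ValueError("peak sets are on different genomes")


def colocalize(
    a: PeakSet, b: PeakSet, max_summit_dist: int = 50
) -> tuple[list[tuple[str, str]], int, int]:
    """Summit-based colocalization between two peak sets.

    A peak in ``a`` colocalizes with a peak in ``b`` when both lie on the
    same chromosome and their summits are within ``max_summit_dist`` bp
    (inclusive).  Returns all qualifying (id_a, id_b) pairs plus the number
    of distinct colocalized peaks in each set (each peak counted once no
    matter how many partners it has).
    """
    _check_same_genome(a, b)
    b_summits = b.summits_by_chrom()
    b_ids: dict[str, list[str]] = {}
    order: dict[str, np.ndarray] = {}
    for chrom in b_summits:
        raw = [(p.summit, p.id) for p in b if p.chrom == chrom]
        raw.sort()
        b_ids[chrom] = [i for _, i in raw]
        order[chrom] = np.asarray([s for s, _ in raw], dtype=np.int64)

    pairs: list[tuple[str, str]] = []
    hit_a: set[str] = set()
    hit_b: set[str] = set()
    for p in a:
        summits = order.get(p.chrom)
        if summits is None or len(summits) == 0:
            continue
        lo = int(np.searchsorted(summits, p.summit - max_summit_dist, side="left"))
        hi = int(np.searchsorted(summits, p.summit + max_summit_dist, side="right"))
        for j in range(lo, hi):
            pairs.append((p.id, b_ids[p.chrom][j]))
            hit_a.add(p.id)
            hit_b.add(b_ids[p.chrom][j])
    return pairs, len(hit_a), len(hit_b)


def stage_only(
    late: PeakSet, early_unfiltered: PeakSet, max_summit_dist: int = 50
) -> PeakSet:
    """Late-stage peaks with no early-stage summit within ``max_summit_dist``.

    ``early_unfiltered`` should be the pre-enrichment-filter early peak set:
    subtracting against the unfiltered calls avoids spuriously labeling a
    site "late only" merely because its early peak fell below the FE cutoff.
    """
    early = early_unfiltered.summits_by_chrom()
    kept = []
    for p in late:
        summits = early.get(p.chrom)
        if summits is not None and len(summits):
            lo = np.searchsorted(summits, p.summit - max_summit_dist, side="left")
            hi = np.searchsorted(summits, p.summit + max_summit_dist, side="right")
            if hi > lo:
                continue
        kept.append(p)
    return PeakSet(label=f"{late.label}-only", peaks=kept, genome=late.genome)


def distance_to_nearest(query: PeakSet, reference: PeakSet) -> np.ndarray:
    """Per-query summit distance to the nearest same-chromosome reference summit.

    Returns a float array ordered as ``query.peaks``; NaN marks queries on
    chromosomes with no reference peak.
    """
    ref = reference.summits_by_chrom()
    out = np.full(len(query), np.nan)
    for i, p in enumerate(query):
        summits = ref.get(p.chrom)
        if summits is None or len(summits) == 0:
            continue
        j = int(np.searchsorted(summits, p.summit))
        best = np.inf
        if j < len(summits):
            best = min(best, abs(int(summits[j]) - p.summit))
        if j > 0:
            best = min(best, abs(int(summits[j - 1]) - p.summit))
        out[i] = best
    return out


def fraction_within(distances: np.ndarray, threshold: int = 40_000) -> float:
    """Percent of queries whose nearest-reference distance is <= ``threshold``.

    The denominator is *all* queries; NaN (no reference on the chromosome)
    counts as not-within.  Returns a percentage in [0, 100].
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        return 0.0
    return 100.0 * float(np.sum(d <= threshold)) / d.size


def summit_window(
    peak: Peak, width: int = 200, chrom_length: int | None = None
) -> tuple[int, int]:
    """The ``width`` bp interval centered on the peak summit, clipped to bounds."""
    if width % 2:
        raise ValueError("window width must be even")
    start = peak.summit - width // 2
    end = peak.summit + width // 2
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    if clipped:
        logger.warning("summit window of peak %s clipped to [%d, %d)", peak.id, start, end)
    return start, end


def random_coordinates(
    genome: dict[str, int], n: int, length: int, seed: int
) -> PeakSet:
    """Random genomic intervals as a background/baseline peak set.

    Chromosomes are sampled proportionally to their length, starts uniformly
    within the valid range; the summit is the interval midpoint.
    """
    if length > min(genome.values()):
        raise ValueError("interval length exceeds the shortest chromosome")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    picks = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    peaks = []
    for i, ci in enumerate(picks):
        chrom = chroms[ci]
        start = int(rng.integers(0, genome[chrom] - length + 1))
        peaks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=start + length,
                summit=start + length // 2,
                fold_enrichment=0.0,
                id=f"rand{i:06d}",
            )
        )
    return PeakSet(label="random", peaks=peaks, genome=dict(genome))
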