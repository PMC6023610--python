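"""Readers and writers for the plain-text genomics formats used here.

narrowPeak (BED6+4), bedGraph, BED6 TSS files, FASTA and TSV tables.  All
interval formats are 0-based half-open.  The narrowPeak summit column is an
offset from ``start``; a value of -1 means "no summit called" and is
replaced by the interval midpoint (logged).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from talegrn.peaks import Peak, PeakSet

logger = logging.getLogger(__name__)


def read_narrowpeak(
    path: str | Path,
    label: str | None = None,
    genome: dict[str, int] | None = None,
) -> PeakSet:
    """Read a narrowPeak (BED6+4) file into a PeakSet.

    Column 7 (signalValue) is taken as fold enrichment; column 10 is the
    summit offset from ``start`` (-1 falls back to the interval midpoint).
    """
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            fe = float(f[6])
            offset = int(f[9])
            if offset < 0:
                offset = (end - start) // 2
                logger.info("%s line %d: no summit, using interval midpoint", path, ln + 1)
            peaks.append(
                Peak(chrom=chrom, start=start, end=end, summit=start + offset,
                     fold_enrichment=fe, id=name)
            )
    return PeakSet(label=label or path.stem, peaks=peaks, genome=genome)


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t0\t.\t"
                f"{p.fold_enrichment!r}\t-1\t-1\t{p.summit - p.start}\n"
            )


def write_fasta(sequences: dict[str, bytes], path: str | Path, width: int = 80) -> None:
    """Write chromosome sequences (uppercase ASCII bytes) wrapped at ``width``."""
    with open(path, "wb") as fh:
        for name, seq in sequences.items():
            fh.write(b">" + name.encode() + b"\n")
            arr = np.frombuffer(seq, dtype=np.uint8)
            n = len(arr)
            nrows = -(-n // width)
            padded = np.full((nrows, width + 1), ord("\n"), dtype=np.uint8)
            pad_len = nrows * width - n
            flat = np.concatenate([arr, np.zeros(pad_len, dtype=np.uint8)])
            padded[:, :width] = flat.reshape(nrows, width)
            out = padded.tobytes()
            if pad_len:
                # drop the zero padding plus its newline, re-add final newline
                out = out[: -(pad_len + 1)] + b"\n"
            fh.write(out)


def write_bed6(
    records: list[tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 of single-base TSS records into a gene table."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    df["tss"] = df["start"]
    return df[["gene_id", "chrom", "tss", "strand"]]


def write_bedgraph(
    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]], path: str | Path
) -> None:
    """Write per-chromosome (starts, ends, values) runs as bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(runs):
            starts, ends, values = runs[chrom]
            lines = "\n".join(
                f"{chrom}\t{s}\t{e}\t{v:g}"
                for s, e, v in zip(starts.tolist(), ends.tolist(), values.tolist())
            )
            if lines:
                fh.write(lines + "\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(files: dict[str, Path], path: str | Path) -> dict:
    manifest = {
        key: {"path": str(p.name), "sha256": file_sha256(p), "bytes": p.stat().st_size}
        for key, p in files.items()
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
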