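"""Reference-point signal matrices around peak summits.

A :class:`SignalTrack` is per-chromosome run-length coverage (bedGraph
semantics: 0-based half-open runs, uncovered bases are zero).  A
:class:`SignalMatrix` holds, for each peak, coverage-weighted mean signal in
fixed-width bins spanning ``[summit - flank, summit + flank)`` — the same
quantity deepTools' computeMatrix produces in reference-point mode with the
conventions used here (flank 1000 or 2000 bp, bin 25 bp).  Bases beyond a
chromosome end contribute zero and the affected rows are flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SignalTrack:
    """Per-chromosome sorted, non-overlapping (starts, ends, values) runs."""

    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    allow_negative: bool = False

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (s, e, v) in self.runs.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s)
            s, e, v = s[order], e[order], v[order]
            if np.any(e[:-1] > s[1:]):
                raise ValueError(f"overlapping runs on {chrom}")
            if not self.allow_negative and np.any(v < 0):
                raise ValueError(f"negative values on {chrom}; pass allow_negative=True for score tracks")
            clean[chrom] = (s, e, v)
        self.runs = clean

    @classmethod
    def from_bedgraph(cls, path: str | Path, allow_negative: bool = False) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
            comment="#",
        )
        runs = {
            chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
            for chrom, g in df.groupby("chrom", sort=True)
        }
        return cls(runs=runs, allow_negative=allow_negative)

    def window_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); out-of-track bases are zero."""
        out = np.zeros(end - start)
        if chrom not in self.runs:
            return out
        s, e, v = self.runs[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        for i in range(lo, hi):
            a = max(int(s[i]), start) - start
            b = min(int(e[i]), end) - start
            if b > a:
                out[a:b] = v[i]
        return out


@dataclass
class SignalMatrix:
    """Rows = peaks (explicit order), columns = bins across the summit window."""

    row_ids: list[str]
    flank: int
    bin: int
    values: np.ndarray
    clipped: np.ndarray | None = None  # rows whose window left the chromosome

    def __post_init__(self) -> None:
        ncols = 2 * self.flank // self.bin
        if self.values.shape != (len(self.row_ids), ncols):
            raise ValueError(
                f"matrix shape {self.values.shape} != ({len(self.row_ids)}, {ncols})"
            )
        if self.clipped is None:
            self.clipped = np.zeros(len(self.row_ids), dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def subset(self, row_ids: list[str]) -> "SignalMatrix":
        index = {r: i for i, r in enumerate(self.row_ids)}
        idx = [index[r] for r in row_ids]
        return SignalMatrix(
            row_ids=list(row_ids), flank=self.flank, bin=self.bin,
            values=self.values[idx].copy(), clipped=self.clipped[idx].copy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(self.values, index=self.row_ids).to_csv(
            path, sep="\t", header=False, float_format="%.6g"
        )
        sidecar = {"flank": self.flank, "bin": self.bin, "n_rows": len(self.row_ids)}
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)
            fh.write("\n")


def compute_matrix(
    track: SignalTrack, peaks, flank: int = 1000, bin: int = 25
) -> SignalMatrix:
    """Binned mean signal in [summit - flank, summit + flank) for every peak.

    Bin values are coverage-weighted means over the bin's bases with
    uncovered and out-of-chromosome bases contributing zero, so a constant
    track yields that constant in every cell regardless of bin width.
    """
    if flank % bin:
        raise ValueError("flank must be divisible by bin")
    ncols = 2 * flank // bin
    genome = getattr(peaks, "genome", None)
    ids, rows, clipped = [], [], []
    for p in peaks:
        ws, we = p.summit - flank, p.summit + flank
        base = np.zeros(2 * flank)
        clip = ws < 0
        if genome is not None and p.chrom in genome:
            clip = clip or we > genome[p.chrom]
        qs, qe = max(ws, 0), we
        vals = track.window_values(p.chrom, qs, qe)
        base[qs - ws: qs - ws + len(vals)] = vals
        rows.append(base.reshape(ncols, bin).mean(axis=1))
        ids.append(p.id)
        clipped.append(clip)
    values = np.vstack(rows) if rows else np.empty((0, ncols))
    return SignalMatrix(
        row_ids=ids, flank=flank, bin=bin, values=values,
        clipped=np.asarray(clipped, dtype=bool),
    )


def mean_profile(matrix: SignalMatrix, rows: list[str] | None = None) -> np.ndarray:
    """Column-wise mean over the selected rows (all rows by default)."""
    if rows is None:
        values = matrix.values
    else:
        if not rows:
            raise ValueError("empty row subset")
        index = {r: i for i, r in enumerate(matrix.row_ids)}
        values = matrix.values[[index[r] for r in rows]]
    return values.mean(axis=0)


def log2_change(
    matrix_t2: SignalMatrix, matrix_t1: SignalMatrix, pseudocount: float = 1.0
) -> tuple[SignalMatrix, np.ndarray]:
    """Cellwise log2((t2 + pc) / (t1 + pc)) plus the per-row mean change."""
    if (
        matrix_t2.row_ids != matrix_t1.row_ids
        or matrix_t2.flank != matrix_t1.flank
        or matrix_t2.bin != matrix_t1.bin
    ):
        raise ValueError("matrices differ in rows, flank or bin")
    vals = np.log2((matrix_t2.values + pseudocount) / (matrix_t1.values + pseudocount))
    out = SignalMatrix(
        row_ids=list(matrix_t2.row_ids), flank=matrix_t2.flank, bin=matrix_t2.bin,
        values=vals, clipped=matrix_t2.clipped | matrix_t1.clipped,
    )
    return out, vals.mean(axis=1)


def average_score(track: SignalTrack, peaks, flank: int = 1000, bin: int = 25) -> np.ndarray:
    """Mean score profile around summits (conservation-score style summary)."""
    return mean_profile(compute_matrix(track, peaks, flank=flank, bin=bin))
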