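"""Chromatin-state classification of TALE-occupied sites.

Two-level scheme mirroring the biology: first, k-means (k=4) on the
H3K4me1 matrix separates sites carrying enhancer/promoter marks (MPADs,
"Modified Prep Associated Domains", ~25% of sites) from unmarked non-MPADs;
second, k-means (k=4) on the concatenated H3K27ac/H3K27me3 matrices splits
MPADs into Classes 1-4, ordered by decreasing H3K27ac — Class 1 is most
active, Class 4 carries the repressive H3K27me3 mark.  Clustering runs on
raw (unscaled) binned signal; final labels depend only on cluster means,
never on raw cluster indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from talegrn.signal import SignalMatrix

MPAD = "MPAD"
NON_MPAD = "nonMPAD"
CLASS_LABELS = ("Class1", "Class2", "Class3", "Class4")


@dataclass
class ClassAssignment:
    """Peak-id -> label mapping with cluster provenance and parameters."""

    labels: dict[str, str]
    cluster_index: dict[str, int] = field(default_factory=dict)
    cluster_means: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def peaks_with_label(self, label: str) -> list[str]:
        return [pid for pid, lab in self.labels.items() if lab == label]

    def counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "peak_id": list(self.labels),
                "label": [self.labels[p] for p in self.labels],
                "cluster_index": [self.cluster_index.get(p, -1) for p in self.labels],
            }
        )
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def kmeans_rows(
    matrix: SignalMatrix, k: int = 4, seed: int = 0, restarts: int = 10
) -> np.ndarray:
    """Cluster matrix rows with k-means++ (best of ``restarts`` by WCSS)."""
    n = len(matrix.row_ids)
    if n < k:
        raise ValueError(f"{n} rows < k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    return km.fit_predict(matrix.values)


def assign_mpad(
    h3k4me1_matrix: SignalMatrix,
    k: int = 4,
    seed: int = 0,
    low_fraction: float = 0.25,
    restarts: int = 10,
) -> ClassAssignment:
    """Label each peak MPAD or non-MPAD from its H3K4me1 signal.

    Rows are clustered (k=4); clusters whose mean row signal falls below
    ``low_fraction`` of the top cluster's mean are non-MPAD.  If no cluster
    falls below the cutoff the single lowest-mean cluster is non-MPAD,
    reproducing the observed 3-marked/1-unmarked topology on any input.
    An all-zero matrix short-circuits to all non-MPAD.
    """
    ids = h3k4me1_matrix.row_ids
    if not np.any(h3k4me1_matrix.values):
        return ClassAssignment(
            labels={pid: NON_MPAD for pid in ids},
            params={"k": k, "seed": seed, "low_fraction": low_fraction, "rule": "all-zero"},
        )
    clusters = kmeans_rows(h3k4me1_matrix, k=k, seed=seed, restarts=restarts)
    row_means = h3k4me1_matrix.row_means()
    cluster_mean = np.array([row_means[clusters == c].mean() for c in range(k)])
    top = cluster_mean.max()
    low = cluster_mean < low_fraction * top
    if not low.any():
        low[int(np.argmin(cluster_mean))] = True
    labels = {
        pid: (NON_MPAD if low[c] else MPAD) for pid, c in zip(ids, clusters)
    }
    means = pd.DataFrame({"H3K4me1": cluster_mean})
    means["label"] = [NON_MPAD if low[c] else MPAD for c in range(k)]
    return ClassAssignment(
        labels=labels,
        cluster_index={pid: int(c) for pid, c in zip(ids, clusters)},
        cluster_means=means,
        params={"k": k, "seed": seed, "low_fraction": low_fraction, "restarts": restarts},
    )


def assign_classes(
    h3k27ac: SignalMatrix,
    h3k27me3: SignalMatrix,
    k: int = 4,
    seed: int = 0,
    restarts: int = 10,
) -> ClassAssignment:
    """Split MPADs into Classes 1-4 on joint H3K27ac/H3K27me3 signal.

    Both matrices must be restricted to MPAD peaks in the same row order.
    Clustering runs on the column-concatenated matrix; clusters are labeled
    Class1..Class4 by mean H3K27ac descending, ties broken by mean H3K27me3
    ascending (more repressive mark -> higher class number).
    """
    if h3k27ac.row_ids != h3k27me3.row_ids:
        raise ValueError("H3K27ac and H3K27me3 matrices have different row order")
    values = np.hstack([h3k27ac.values, h3k27me3.values])
    n = len(h3k27ac.row_ids)
    if n < k:
        raise ValueError(f"{n} rows < k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    clusters = km.fit_predict(values)
    ac_means = np.array([h3k27ac.values[clusters == c].mean() for c in range(k)])
    me3_means = np.array([h3k27me3.values[clusters == c].mean() for c in range(k)])
    order = sorted(range(k), key=lambda c: (-ac_means[c], me3_means[c]))
    label_of = {c: CLASS_LABELS[rank] for rank, c in enumerate(order)}
    ids = h3k27ac.row_ids
    means = pd.DataFrame(
        {"H3K27ac": ac_means, "H3K27me3": me3_means,
         "label": [label_of[c] for c in range(k)]}
    )
    return ClassAssignment(
        labels={pid: label_of[int(c)] for pid, c in zip(ids, clusters)},
        cluster_index={pid: int(c) for pid, c in zip(ids, clusters)},
        cluster_means=means,
        params={"k": k, "seed": seed, "restarts": restarts},
    )


def classify_peaks(
    h3k4me1: SignalMatrix,
    h3k27ac: SignalMatrix,
    h3k27me3: SignalMatrix,
    k: int = 4,
    seed: int = 0,
    low_fraction: float = 0.25,
) -> ClassAssignment:
    """Full two-level labeling: nonMPAD or Class1..Class4 for every peak."""
    mpad = assign_mpad(h3k4me1, k=k, seed=seed, low_fraction=low_fraction)
    mpad_ids = [pid for pid in h3k4me1.row_ids if mpad.labels[pid] == MPAD]
    labels = dict(mpad.labels)
    cluster_index = dict(mpad.cluster_index)
    means = None
    if len(mpad_ids) >= k:
        classes = assign_classes(
            h3k27ac.subset(mpad_ids), h3k27me3.subset(mpad_ids), k=k, seed=seed
        )
        labels.update(classes.labels)
        cluster_index.update(classes.cluster_index)
        means = classes.cluster_means
    return ClassAssignment(
        labels=labels,
        cluster_index=cluster_index,
        cluster_means=means,
        params={"k": k, "seed": seed, "low_fraction": low_fraction},
    )
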