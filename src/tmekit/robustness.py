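"""Clustering stability by normalized mutual information.

Two protocols: down-sampling to fixed fractions with many replicates, and
leave-one-patient-out.  Re-clustering is delegated to a caller-supplied
callback (a cell subset in, labels out); a k-means reference callback is
provided.  NMI uses the arithmetic-mean normalization by default.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from tmekit.core_io import CellAnnotation, ExpressionMatrix

#: cluster_fn contract: (matrix restricted to a cell subset, replicate seed)
#: -> one label per cell of the subset, in order.
ClusterFn = Callable[[ExpressionMatrix, int], np.ndarray]

REPORT_COLUMNS = ("protocol", "condition", "replicate", "n_cells", "nmi")


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi(
    labels_a: Sequence, labels_b: Sequence, average_method: str = "arithmetic"
) -> float:
    """Normalized mutual information between two labelings of the same items.

    I(A;B) divided by the arithmetic mean of the entropies (or min / max /
    geometric per ``average_method``).  1 for identical partitions up to
    renaming; 0 when either labeling is constant while the other is not.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty labelings")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(contingency, (ai, bi), 1.0)
    n = contingency.sum()
    ha = _entropy(contingency.sum(axis=1))
    hb = _entropy(contingency.sum(axis=0))
    nz = contingency > 0
    pij = contingency[nz] / n
    pa = (contingency.sum(axis=1) / n)[np.nonzero(nz)[0]]
    pb = (contingency.sum(axis=0) / n)[np.nonzero(nz)[1]]
    mi = float((pij * np.log(pij / (pa * pb))).sum())
    if average_method == "arithmetic":
        denom = (ha + hb) / 2.0
    elif average_method == "min":
        denom = min(ha, hb)
    elif average_method == "max":
        denom = max(ha, hb)
    elif average_method == "geometric":
        denom = float(np.sqrt(ha * hb))
    else:
        raise ValueError("unknown average_method")
    if denom == 0:
        # both labelings constant: identical partitions by convention
        return 1.0 if ha == hb == 0 else 0.0
    return max(0.0, min(1.0, mi / denom))


def kmeans_callback(k: int, n_init: int = 10) -> ClusterFn:
    """Reference re-clustering callback: k-means on the normalized matrix."""

    def fn(mat: ExpressionMatrix, seed: int) -> np.ndarray:
        x = (mat.normalized if mat.normalized is not None else mat.counts).T
        return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit_predict(x)

    return fn


def random_label_callback(k: int) -> ClusterFn:
    """Null callback assigning uniform random labels (calibration floor)."""

    def fn(mat: ExpressionMatrix, seed: int) -> np.ndarray:
        return np.random.default_rng(seed).integers(0, k, mat.n_cells)

    return fn


def downsample_robustness(
    mat: ExpressionMatrix,
    benchmark_labels: Sequence,
    cluster_fn: ClusterFn,
    fractions: Sequence[float] = (1 / 2, 1 / 3, 1 / 4, 1 / 5),
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """NMI of re-clustered down-samples against the benchmark labeling.

    Cells are sampled without replacement at each fraction, ``n_reps`` times;
    replicate seeds derive from ``seed`` via a counter.
    """
    benchmark = np.asarray(benchmark_labels)
    if benchmark.shape[0] != mat.n_cells:
        raise ValueError("benchmark labels must cover all cells")
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    rows = []
    counter = 0
    for frac in fractions:
        n_take = max(1, int(round(frac * mat.n_cells)))
        for rep in range(n_reps):
            rep_seed = seed * 100_000 + counter
            counter += 1
            rng = np.random.default_rng(rep_seed)
            idx = rng.choice(mat.n_cells, size=n_take, replace=False)
            labels = cluster_fn(mat.subset_cells(idx), rep_seed)
            rows.append(
                {
                    "protocol": "downsample",
                    "condition": f"{frac:g}",
                    "replicate": rep,
                    "n_cells": n_take,
                    "nmi": nmi(labels, benchmark[idx]),
                }
            )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def leave_one_patient_out(
    mat: ExpressionMatrix,
    ann: CellAnnotation,
    benchmark_labels: Sequence,
    cluster_fn: ClusterFn,
    seed: int = 0,
) -> pd.DataFrame:
    """Hold out each patient in turn; NMI on the retained cells."""
    benchmark = np.asarray(benchmark_labels)
    if benchmark.shape[0] != mat.n_cells:
        raise ValueError("benchmark labels must cover all cells")
    ann = ann.aligned_to(mat)
    patients = ann.column("patient")
    unique_patients = sorted(pd.unique(patients))
    if len(unique_patients) < 2:
        raise ValueError("need >= 2 patients")
    rows = []
    for i, patient in enumerate(unique_patients):
        keep = patients != patient
        idx = np.flatnonzero(keep)
        labels = cluster_fn(mat.subset_cells(idx), seed * 100_000 + i)
        rows.append(
            {
                "protocol": "leave_one_out",
                "condition": patient,
                "replicate": 0,
                "n_cells": int(keep.sum()),
                "nmi": nmi(labels, benchmark[idx]),
            }
        )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def summarize_report(report: pd.DataFrame) -> pd.DataFrame:
    """Mean +- sd of NMI per (protocol, condition)."""
    return (
        report.groupby(["protocol", "condition"])["nmi"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
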