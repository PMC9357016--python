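"""Cytotoxic T cell exhaustion staging.

CTLs are subclustered by k-means on their normalized effector-molecule
expression, subclusters are relabeled KM1..KMk in decreasing order of mean
effector expression, the lowest-effector subcluster is flagged exhausted,
and the next-lowest is flagged pre-exhausted when it shares enough of its
marker genes with the exhausted subcluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from tmekit.core_io import CellAnnotation, ExpressionMatrix
from tmekit.markers import find_markers

#: Printed T cell exhaustion markers used as the flagging default.
EXHAUSTION_GENES = ("CTLA4", "PDCD1", "LAG3", "CD27", "CD52", "ICOS")

#: Conventional CTL effector molecules; override with the study-specific list.
DEFAULT_EFFECTOR_GENES = ("GZMB", "PRF1", "GNLY", "IFNG", "NKG7")


@dataclass
class ExhaustionResult:
    cell_ids: list[str]
    labels: np.ndarray  # KM label per cell
    summary: pd.DataFrame  # one row per subcluster, KM1..KMk
    overlap_fraction: float | None = None
    _submatrix: ExpressionMatrix | None = field(default=None, repr=False)
    _subann: CellAnnotation | None = field(default=None, repr=False)


def kmeans_states(
    mat: ExpressionMatrix,
    ann: CellAnnotation,
    cells: list[str] | np.ndarray,
    effector_genes: list[str] = list(DEFAULT_EFFECTOR_GENES),
    k: int = 5,
    seed: int = 0,
    n_init: int = 10,
) -> ExhaustionResult:
    """K-means over the normalized effector submatrix of the CTL cells.

    Subclusters are renamed KM1..KMk by decreasing mean effector expression;
    ties fall back to the k-means component index.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not list(effector_genes):
        raise ValueError("effector gene set is empty")
    if mat.normalized is None:
        raise ValueError("normalized layer required")
    ann = ann.aligned_to(mat)
    cell_set = set(cells)
    keep = np.array([c in cell_set for c in mat.cell_ids])
    if keep.sum() < k:
        raise ValueError(f"only {keep.sum()} CTL cells for k={k}")
    sub = mat.subset_cells(keep)
    subann = CellAnnotation(ann.df.loc[keep].reset_index(drop=True))

    x = sub.normalized[sub.gene_index(effector_genes)].T  # cells x effectors
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(x)

    effector_mean = np.array(
        [x[raw == i].mean() if (raw == i).any() else -np.inf for i in range(k)]
    )
    order = sorted(range(k), key=lambda i: (-effector_mean[i], i))
    rename = {comp: f"KM{rank + 1}" for rank, comp in enumerate(order)}
    labels = np.array([rename[r] for r in raw], dtype=object)

    summary = pd.DataFrame(
        {
            "subcluster": [f"KM{r + 1}" for r in range(k)],
            "n_cells": [int((raw == comp).sum()) for comp in order],
            "effector_score": effector_mean[order],
            "state": "non_exhausted",
        }
    )
    subann = CellAnnotation(subann.df.assign(cluster=labels))
    return ExhaustionResult(
        cell_ids=sub.cell_ids,
        labels=labels,
        summary=summary,
        _submatrix=sub,
        _subann=subann,
    )


def _marker_genes(result: ExhaustionResult, subcluster: str, **kwargs) -> set[str]:
    tab = find_markers(result._submatrix, result._subann, subcluster, **kwargs)
    return set(tab["gene"])


def flag_states(
    result: ExhaustionResult,
    exhaustion_genes: list[str] = list(EXHAUSTION_GENES),
    overlap_threshold: float = 0.5,
    marker_kwargs: dict | None = None,
) -> ExhaustionResult:
    """Fill exhaustion states on a staged result.

    The lowest-effector subcluster (KMk) is exhausted.  KM(k-1) is
    pre-exhausted iff the fraction of its markers (vs the rest of the CTLs)
    that also belong to the exhausted subcluster's marker set reaches
    ``overlap_threshold``.  With k = 2 no pre-exhausted state is assigned.
    """
    if result._submatrix is None:
        raise ValueError("result was not produced by kmeans_states")
    k = len(result.summary)
    sub = result._submatrix
    present = [g for g in exhaustion_genes if g in sub.gene_ids]
    if present:
        scores = sub.normalized[sub.gene_index(present)].mean(axis=0)
        result.summary["exhaustion_score"] = [
            float(scores[result.labels == s].mean()) if (result.labels == s).any() else np.nan
            for s in result.summary["subcluster"]
        ]
    else:
        result.summary["exhaustion_score"] = np.nan

    states = ["non_exhausted"] * k
    states[k - 1] = "exhausted"
    overlap = None
    if k > 2:
        kwargs = marker_kwargs or {}
        exhausted_markers = _marker_genes(result, f"KM{k}", **kwargs)
        candidate_markers = _marker_genes(result, f"KM{k - 1}", **kwargs)
        if candidate_markers:
            overlap = len(candidate_markers & exhausted_markers) / len(candidate_markers)
        else:
            overlap = 0.0
        if overlap >= overlap_threshold:
            states[k - 2] = "pre_exhausted"
    result.summary["state"] = states
    result.overlap_fraction = overlap
    return result


def per_cell_states(result: ExhaustionResult) -> pd.DataFrame:
    """Long-format per-cell table (cell_id, subcluster, state)."""
    state_of = dict(zip(result.summary["subcluster"], result.summary["state"]))
    return pd.DataFrame(
        {
            "cell_id": result.cell_ids,
            "subcluster": result.labels,
            "state": [state_of[s] for s in result.labels],
        }
    )
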