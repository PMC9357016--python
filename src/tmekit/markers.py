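"""Cluster marker detection by the three-criterion rule.

A gene is a marker of a cluster iff (i) its two-sided Wilcoxon rank-sum
p-value, Bonferroni-adjusted over all genes in the matrix, is below ``alpha``;
(ii) its linear-scale mean expression in the cluster is at least ``min_fc``
times the mean outside; and (iii) its detection percentage in the cluster
exceeds the outside percentage by at least ``min_pct_diff``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from tmekit.core_io import CellAnnotation, ExpressionMatrix

MARKER_COLUMNS = ("cluster", "gene", "fold_change", "pct_in", "pct_out", "p_raw", "p_adj")

_EPS = 1e-9


def _admit(
    mat: ExpressionMatrix,
    in_mask: np.ndarray,
    label: str,
    min_fc: float,
    min_pct_diff: float,
    alpha: float,
    fc_scale: str,
) -> pd.DataFrame:
    """Run the admission rule for one in/out split over all genes."""
    norm = mat.normalized
    x = norm[:, in_mask]
    y = norm[:, ~in_mask]
    if x.shape[1] < 3 or y.shape[1] < 3:
        raise ValueError("need >= 3 cells on each side of the contrast")

    if fc_scale == "linear":
        lin = np.power(2.0, norm) - 1.0
        mean_in = lin[:, in_mask].mean(axis=1)
        mean_out = lin[:, ~in_mask].mean(axis=1)
    elif fc_scale == "log":
        mean_in = x.mean(axis=1)
        mean_out = y.mean(axis=1)
    else:
        raise ValueError("fc_scale must be 'linear' or 'log'")
    fold_change = (mean_in + _EPS) / (mean_out + _EPS)
    pct_in = (x > 0).mean(axis=1)
    pct_out = (y > 0).mean(axis=1)

    nonzero = norm.max(axis=1) > 0  # all-zero genes skipped silently
    p_raw = np.ones(mat.n_genes)
    if nonzero.any():
        res = stats.mannwhitneyu(
            x[nonzero], y[nonzero], axis=1, alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
        p_raw[nonzero] = res.pvalue
    p_adj = np.minimum(1.0, p_raw * mat.n_genes)  # Bonferroni over ALL genes

    admitted = (
        nonzero
        & (p_adj < alpha)
        & (fold_change >= min_fc)
        & (pct_in - pct_out >= min_pct_diff)
    )
    out = pd.DataFrame(
        {
            "cluster": label,
            "gene": np.array(mat.gene_ids, dtype=object)[admitted],
            "fold_change": fold_change[admitted],
            "pct_in": pct_in[admitted],
            "pct_out": pct_out[admitted],
            "p_raw": p_raw[admitted],
            "p_adj": p_adj[admitted],
        }
    )
    return out.sort_values("fold_change", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def find_markers(
    mat: ExpressionMatrix,
    ann: CellAnnotation,
    cluster: str,
    min_fc: float = 2.0,
    min_pct_diff: float = 0.20,
    alpha: float = 0.01,
    fc_scale: str = "linear",
) -> pd.DataFrame:
    """Markers of ``cluster`` versus all other cells, sorted by fold change."""
    if mat.normalized is None:
        raise ValueError("normalized layer required; run normalize_counts first")
    ann = ann.aligned_to(mat)
    clusters = ann.column("cluster")
    if cluster not in clusters:
        raise ValueError(f"unknown cluster {cluster!r}")
    return _admit(mat, clusters == cluster, cluster, min_fc, min_pct_diff, alpha, fc_scale)


def find_all_markers(
    mat: ExpressionMatrix,
    ann: CellAnnotation,
    min_fc: float = 2.0,
    min_pct_diff: float = 0.20,
    alpha: float = 0.01,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Concatenated marker tables for every cluster with enough cells."""
    ann = ann.aligned_to(mat)
    clusters = ann.column("cluster")
    tables = []
    for c in pd.unique(clusters):
        n_in = int((clusters == c).sum())
        if n_in < min_cells or len(clusters) - n_in < min_cells:
            continue
        tables.append(find_markers(mat, ann, c, min_fc, min_pct_diff, alpha))
    if not tables:
        return pd.DataFrame(columns=list(MARKER_COLUMNS))
    return pd.concat(tables, ignore_index=True)


def contrast_signature(
    mat: ExpressionMatrix,
    ann: CellAnnotation,
    group_a: set[str],
    group_b: set[str],
    min_fc: float = 2.0,
    min_pct_diff: float = 0.20,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Markers of pooled ``group_a`` cells against pooled ``group_b`` cells.

    Only cells belonging to either group enter the contrast; the admission
    rule is the same as :func:`find_markers`.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if mat.normalized is None:
        raise ValueError("normalized layer required; run normalize_counts first")
    ann = ann.aligned_to(mat)
    clusters = ann.column("cluster")
    keep = np.isin(clusters, list(group_a | group_b))
    sub = mat.subset_cells(keep)
    in_mask = np.isin(clusters[keep], list(group_a))
    label = "+".join(sorted(group_a))
    return _admit(sub, in_mask, label, min_fc, min_pct_diff, alpha, "linear")
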