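"""Cross-dataset cluster similarity.

Two schemes: a weighted shared-marker score (sum over shared marker genes of
the product of the two clusters' fold changes) for datasets where only marker
tables are available, and a ridge-penalized multinomial logistic classifier
trained on a reference dataset and averaged over query-cluster cells when raw
expression is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from tmekit.core_io import CellAnnotation, ExpressionMatrix
from tmekit.markers import find_all_markers


def weighted_fc_similarity(
    markers_q: pd.DataFrame,
    markers_r: pd.DataFrame,
    fc_cap: float = 100.0,
) -> pd.DataFrame:
    """S[q, r] = sum over shared markers of FC_q(gene) * FC_r(gene).

    Fold changes are capped at ``fc_cap`` so single near-zero-denominator
    genes cannot dominate the sum.  Rows are query clusters, columns are
    reference clusters.
    """
    for name, tab in (("query", markers_q), ("reference", markers_r)):
        if tab.empty:
            raise ValueError(f"{name} marker table is empty")
        if tab.duplicated(["cluster", "gene"]).any():
            raise ValueError(f"{name} marker table has duplicated (cluster, gene) rows")

    def pivot(tab: pd.DataFrame) -> pd.DataFrame:
        wide = tab.pivot(index="gene", columns="cluster", values="fold_change")
        return wide.clip(upper=fc_cap).fillna(0.0)

    wq, wr = pivot(markers_q), pivot(markers_r)
    shared = wq.index.intersection(wr.index)
    if len(shared) == 0:
        scores = np.zeros((wq.shape[1], wr.shape[1]))
    else:
        scores = wq.loc[shared].to_numpy().T @ wr.loc[shared].to_numpy()
    return pd.DataFrame(scores, index=wq.columns, columns=wr.columns)


def _feature_matrix(mat: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    idx = mat.gene_index(genes)
    return mat.normalized[idx].T  # cells x genes


def select_feature_genes(
    mat: ExpressionMatrix,
    ann: CellAnnotation,
    top_n: int = 50,
    **marker_kwargs,
) -> list[str]:
    """Union of the top ``top_n`` markers (by fold change) per cluster."""
    markers = find_all_markers(mat, ann, **marker_kwargs)
    picked: list[str] = []
    for _, sub in markers.groupby("cluster", sort=True):
        picked.extend(sub.nlargest(top_n, "fold_change")["gene"])
    return sorted(set(picked))


def classifier_similarity(
    reference: tuple[ExpressionMatrix, CellAnnotation],
    query: tuple[ExpressionMatrix, CellAnnotation],
    feature_genes: list[str],
    penalty_c: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean predicted reference-class probability per query cluster.

    A multinomial logistic regression with L2 penalty is fit on the
    reference's normalized expression of ``feature_genes`` (per-gene
    standardized); similarity of query cluster q to reference cluster r is
    the mean predicted probability of r over the cells of q.  Rows sum to 1.
    """
    ref_mat, ref_ann = reference
    q_mat, q_ann = query
    if ref_mat.normalized is None or q_mat.normalized is None:
        raise ValueError("both datasets need a normalized layer")
    ref_ann = ref_ann.aligned_to(ref_mat)
    q_ann = q_ann.aligned_to(q_mat)
    ref_clusters = ref_ann.column("cluster")
    if len(np.unique(ref_clusters)) < 2:
        raise ValueError("reference must have >= 2 clusters")

    x_ref = _feature_matrix(ref_mat, feature_genes)
    x_q = _feature_matrix(q_mat, feature_genes)
    mu = x_ref.mean(axis=0)
    sd = x_ref.std(axis=0)
    sd[sd == 0] = 1.0
    x_ref = (x_ref - mu) / sd
    x_q = (x_q - mu) / sd

    model = LogisticRegression(C=penalty_c, max_iter=2000, random_state=seed)
    model.fit(x_ref, ref_clusters)
    probs = model.predict_proba(x_q)

    q_clusters = q_ann.column("cluster")
    rows = {}
    for c in pd.unique(q_clusters):
        rows[c] = probs[q_clusters == c].mean(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=model.classes_)
    return out.sort_index()
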