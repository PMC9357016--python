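"""Ligand-receptor interaction scoring between cell clusters.

The interaction intensity of an L-R pair for an ordered cluster pair (A, B)
is the product of the mean normalized ligand expression in A and the mean
normalized receptor expression in B.  Significance comes from permuting the
cluster tags of all cells and recomputing every intensity; Bonferroni
correction is applied across the L-R pairs tested for each cluster pair.
A pair is called significant when intensity > 1 and adjusted p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from tmekit.core_io import CellAnnotation, ExpressionMatrix

RESULT_COLUMNS = (
    "cluster_L",
    "cluster_R",
    "ligand",
    "receptor",
    "intensity",
    "p_raw",
    "p_adj",
    "significant",
)


@dataclass
class LRPairSet:
    """Curated ligand -> receptor pairs with a provenance column."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"ligand", "receptor"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"pair table missing columns: {sorted(missing)}")
        if "source" not in self.df.columns:
            self.df = self.df.assign(source="unknown")
        if (self.df["ligand"] == "").any() or (self.df["receptor"] == "").any():
            raise ValueError("empty gene names in pair table")
        dup = self.df.duplicated(["ligand", "receptor"])
        if dup.any():
            warnings.warn(f"collapsing {int(dup.sum())} duplicate L-R rows", stacklevel=2)
            self.df = self.df.loc[~dup]
        self.df = self.df.reset_index(drop=True)
        self.df["self_pair"] = self.df["ligand"] == self.df["receptor"]

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_csv(cls, path) -> "LRPairSet":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def eligible_clusters(
    ann: CellAnnotation,
    tissue: str,
    min_cells: int = 5,
    min_fraction: float = 0.10,
    fraction_base: str = "lineage",
) -> set[str]:
    """Clusters with enough cells and a large enough share of the tissue.

    ``fraction_base='lineage'`` measures each cluster against the cells of
    its own lineage in the tissue; ``'all'`` against every cell in the
    tissue.
    """
    df = ann.df
    if tissue not in set(df["tissue"]):
        raise ValueError(f"unknown tissue {tissue!r}")
    sub = df[df["tissue"] == tissue]
    sizes = sub.groupby("cluster").size()
    out = set()
    for cluster, n in sizes.items():
        if n < min_cells:
            continue
        if fraction_base == "lineage":
            lineage = sub.loc[sub["cluster"] == cluster, "lineage"].iloc[0]
            base = (sub["lineage"] == lineage).sum()
        elif fraction_base == "all":
            base = len(sub)
        else:
            raise ValueError("fraction_base must be 'lineage' or 'all'")
        if base > 0 and n / base >= min_fraction:
            out.add(cluster)
    return out


def _cluster_means(
    norm_sub: np.ndarray, labels_idx: np.ndarray, n_clusters: int
) -> np.ndarray:
    """Mean normalized expression per cluster: genes x clusters."""
    sums = np.zeros((norm_sub.shape[0], n_clusters))
    np.add.at(sums.T, labels_idx, norm_sub.T)
    counts = np.bincount(labels_idx, minlength=n_clusters)
    return sums / counts


def interaction_intensity(
    mat: ExpressionMatrix,
    ann: CellAnnotation,
    cluster_l: str,
    cluster_r: str,
    ligand: str,
    receptor: str,
    min_expr: float = 1.0,
) -> float | None:
    """Product-of-means intensity; ``None`` when either mean is below
    ``min_expr`` (the expression floor)."""
    if mat.normalized is None:
        raise ValueError("normalized layer required")
    ann = ann.aligned_to(mat)
    clusters = ann.column("cluster")
    for c in (cluster_l, cluster_r):
        if not (clusters == c).any():
            raise ValueError(f"empty or unknown cluster {c!r}")
    li, ri = mat.gene_index([ligand, receptor])
    mean_l = mat.normalized[li, clusters == cluster_l].mean()
    mean_r = mat.normalized[ri, clusters == cluster_r].mean()
    if mean_l < min_expr or mean_r < min_expr:
        return None
    return float(mean_l * mean_r)


def permutation_test(
    mat: ExpressionMatrix,
    ann: CellAnnotation,
    pairs: LRPairSet,
    clusters: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "ge",
    min_expr: float = 1.0,
    intensity_cut: float = 1.0,
    alpha: float = 0.01,
    bonferroni: str = "per_cluster_pair",
    include_self: bool = False,
) -> pd.DataFrame:
    """Permutation p-values for every L-R pair over every ordered cluster pair.

    Cluster tags of all cells are shuffled jointly each permutation and all
    intensities recomputed; ``p_raw`` is the fraction of permutations whose
    intensity is >= (``tail='ge'``) or > (``'gt'``, the strict wording) the
    observed value.  Pairs whose ligand or receptor cluster mean falls below
    ``min_expr`` are filtered before testing and excluded from the Bonferroni
    family.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("ge", "gt"):
        raise ValueError("tail must be 'ge' or 'gt'")
    if mat.normalized is None:
        raise ValueError("normalized layer required")
    ann = ann.aligned_to(mat)
    labels = ann.column("cluster")
    if clusters is None:
        clusters = sorted(pd.unique(labels))
    else:
        clusters = sorted(clusters)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    keep = np.isin(labels, clusters)
    sub = mat.subset_cells(keep)
    labels = labels[keep]
    cl_index = {c: i for i, c in enumerate(clusters)}
    labels_idx = np.array([cl_index[c] for c in labels])
    n_clusters = len(clusters)

    genes = sorted(set(pairs.df["ligand"]) | set(pairs.df["receptor"]))
    g_index = {g: i for i, g in enumerate(genes)}
    norm_sub = sub.normalized[sub.gene_index(genes)]
    lig_idx = pairs.df["ligand"].map(g_index).to_numpy()
    rec_idx = pairs.df["receptor"].map(g_index).to_numpy()

    means = _cluster_means(norm_sub, labels_idx, n_clusters)  # genes x clusters
    # observed intensity: pairs x cluster_L x cluster_R
    obs = means[lig_idx][:, :, None] * means[rec_idx][:, None, :]
    tested = (means[lig_idx][:, :, None] >= min_expr) & (
        means[rec_idx][:, None, :] >= min_expr
    )
    if not include_self:
        tested &= ~np.eye(n_clusters, dtype=bool)[None, :, :]

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(len(labels_idx))
        pmeans = _cluster_means(norm_sub, labels_idx[perm], n_clusters)
        pint = pmeans[lig_idx][:, :, None] * pmeans[rec_idx][:, None, :]
        if tail == "ge":
            exceed += pint >= obs
        else:
            exceed += pint > obs
    p_raw = exceed / n_perm

    if bonferroni == "per_cluster_pair":
        m = tested.sum(axis=0)[None, :, :]  # tested L-R pairs per cluster pair
    elif bonferroni == "global":
        m = tested.sum()
    else:
        raise ValueError("bonferroni must be 'per_cluster_pair' or 'global'")
    p_adj = np.minimum(1.0, p_raw * m)

    pi, ci, cj = np.nonzero(tested)
    out = pd.DataFrame(
        {
            "cluster_L": np.array(clusters, dtype=object)[ci],
            "cluster_R": np.array(clusters, dtype=object)[cj],
            "ligand": pairs.df["ligand"].to_numpy()[pi],
            "receptor": pairs.df["receptor"].to_numpy()[pi],
            "intensity": obs[pi, ci, cj],
            "p_raw": p_raw[pi, ci, cj],
            "p_adj": p_adj[pi, ci, cj],
        }
    )
    out["significant"] = (out["intensity"] > intensity_cut) & (out["p_adj"] < alpha)
    return out.sort_values(["cluster_L", "cluster_R", "ligand", "receptor"]).reset_index(
        drop=True
    )


def communication_network(
    result: pd.DataFrame,
    ann: CellAnnotation,
    tissue: str | None = None,
    weighting: str = "cells_product",
) -> pd.DataFrame:
    """Directed cluster->cluster edges weighted by significant L-R pair counts.

    ``cells_product``: count * n_L * n_R / N^2; ``cells_sum``:
    count * (n_L + n_R) / N; ``count``: the raw number of significant pairs.
    Cluster sizes are taken within ``tissue`` when given.
    """
    df = ann.df if tissue is None else ann.df[ann.df["tissue"] == tissue]
    sizes = df.groupby("cluster").size()
    total = len(df)
    sig = result[result["significant"]]
    edges = []
    for (cl, cr), grp in sig.groupby(["cluster_L", "cluster_R"]):
        count = len(grp)
        n_l = int(sizes.get(cl, 0))
        n_r = int(sizes.get(cr, 0))
        if weighting == "cells_product":
            weight = count * n_l * n_r / total**2
        elif weighting == "cells_sum":
            weight = count * (n_l + n_r) / total
        elif weighting == "count":
            weight = float(count)
        else:
            raise ValueError("weighting must be cells_product, cells_sum or count")
        edges.append(
            {
                "cluster_L": cl,
                "cluster_R": cr,
                "n_significant": count,
                "weight": weight,
                "tissue": tissue,
            }
        )
    return pd.DataFrame(
        edges, columns=["cluster_L", "cluster_R", "n_significant", "weight", "tissue"]
    )


def pathway_activity(
    mat: ExpressionMatrix, gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-cell pathway score: mean across member genes of the per-gene
    z-scored normalized expression.  A lightweight stand-in for sample-rank
    enrichment scores; cells x pathways."""
    if mat.normalized is None:
        raise ValueError("normalized layer required")
    norm = mat.normalized
    mu = norm.mean(axis=1, keepdims=True)
    sd = norm.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (norm - mu) / sd
    scores = {}
    for name, members in gene_sets.items():
        present = [g for g in members if g in mat.gene_ids]
        if not present:
            warnings.warn(f"pathway {name!r}: no member genes in matrix", stacklevel=2)
            continue
        scores[name] = z[mat.gene_index(present)].mean(axis=0)
    return pd.DataFrame(scores, index=mat.cell_ids)


def ligand_pathway_network(
    mat: ExpressionMatrix,
    ann: CellAnnotation,
    cells: list[str],
    ligands: list[str],
    pathway_scores: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Bipartite ligand-pathway edges by Spearman correlation over ``cells``.

    One row per (ligand, pathway) with signed rho, p and an ``edge`` flag
    (p < ``alpha``).  Constant ligand vectors are skipped with a warning.
    """
    if mat.normalized is None:
        raise ValueError("normalized layer required")
    missing = [c for c in cells if c not in set(pathway_scores.index)]
    if missing:
        raise ValueError(f"cells without pathway scores: {missing[:5]}")
    sub = mat.subset_cells(np.isin(mat.cell_ids, cells))
    scores = pathway_scores.loc[sub.cell_ids]
    rows = []
    for ligand in ligands:
        expr = sub.normalized[sub.gene_index([ligand])[0]]
        if np.ptp(expr) == 0:
            warnings.warn(f"ligand {ligand!r} constant; skipped", stacklevel=2)
            continue
        for pathway in scores.columns:
            rho, p = stats.spearmanr(expr, scores[pathway].to_numpy())
            rows.append(
                {
                    "ligand": ligand,
                    "pathway": pathway,
                    "rho": float(rho),
                    "p": float(p),
                    "edge": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows, columns=["ligand", "pathway", "rho", "p", "edge"])
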