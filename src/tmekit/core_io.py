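"""Data model, MTX/TSV readers and writers, per-cell QC, count normalization.

The on-disk layout follows the droplet-sequencing convention: a MatrixMarket
coordinate file (genes x cells, 1-based, integer field) accompanied by a
``genes.tsv`` and a ``barcodes.tsv`` holding one identifier per row.  Cell
metadata lives in a separate annotation TSV with a header row and the columns
``cell_id``, ``cluster``, ``tissue``, ``patient``, ``lineage``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

TISSUES = ("NTL", "PT", "PVTT", "MLN")

ANNOTATION_COLUMNS = ("cell_id", "cluster", "tissue", "patient", "lineage")

#: QC failure reasons, checked in this order; the first failing rule is reported.
QC_REASONS = ("low_umi", "low_genes", "high_genes", "high_mito")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class ExpressionMatrix:
    """Genes x cells raw counts with an optional log2-normalized layer."""

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized layer shape differs from counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of ``genes``; raises KeyError listing the missing ones."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            counts=self.counts[:, idx],
            normalized=None if self.normalized is None else self.normalized[:, idx],
        )


@dataclass
class CellAnnotation:
    """Per-cell cluster / tissue / patient / lineage labels."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        self.df = self.df.loc[:, list(ANNOTATION_COLUMNS)].reset_index(drop=True)
        if self.df["cell_id"].duplicated().any():
            dups = self.df.loc[self.df["cell_id"].duplicated(), "cell_id"].tolist()
            raise ValueError(f"duplicate annotation records for cells: {dups[:5]}")
        bad = set(self.df["tissue"].unique()) - set(TISSUES)
        if bad:
            raise ValueError(f"tissue labels outside {TISSUES}: {sorted(bad)}")

    @property
    def cell_ids(self) -> list[str]:
        return self.df["cell_id"].tolist()

    def aligned_to(self, mat: ExpressionMatrix) -> "CellAnnotation":
        """Reorder to the matrix's cell order; every cell must be annotated."""
        indexed = self.df.set_index("cell_id")
        missing = [c for c in mat.cell_ids if c not in indexed.index]
        if missing:
            raise ValueError(f"cells without annotation: {missing[:5]}")
        out = indexed.loc[mat.cell_ids].reset_index()
        return CellAnnotation(out)

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()


@dataclass(frozen=True)
class QCThresholds:
    min_umi: int = 200
    min_genes: int = 200
    max_genes: int = 8000
    max_mito_fraction: float = 0.10
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def _read_id_column(path: str | Path) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return ids.iloc[:, 0].tolist()


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a MatrixMarket + genes.tsv + barcodes.tsv triplet.

    Returns an :class:`ExpressionMatrix` with ``counts`` populated and no
    normalized layer.  The matrix is oriented genes x cells.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except ValueError as exc:
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    genes = _read_id_column(genes_path)
    barcodes = _read_id_column(barcodes_path)
    if len(genes) != dense.shape[0]:
        raise FormatError(
            f"{genes_path}: {len(genes)} gene rows but matrix has {dense.shape[0]} rows"
        )
    if len(barcodes) != dense.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcode rows but matrix has "
            f"{dense.shape[1]} columns"
        )
    if not np.all(dense == np.round(dense)):
        raise ValueError(f"{matrix_path}: non-integer count entries")
    return ExpressionMatrix(genes, barcodes, dense.astype(np.int64))


def write_expression(
    mat: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write the triplet read by :func:`read_expression` (1-based, integer)."""
    sparse = scipy.sparse.coo_matrix(mat.counts)
    scipy.io.mmwrite(str(matrix_path), sparse, field="integer")
    pd.Series(mat.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(mat.cell_ids).to_csv(barcodes_path, sep="\t", header=False, index=False)


def read_annotation(path: str | Path) -> CellAnnotation:
    return CellAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    ann.df.to_csv(path, sep="\t", index=False)


def qc_filter(
    mat: ExpressionMatrix,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove low-quality cells; report each removed cell's first failing rule.

    A cell is kept iff total UMI >= ``min_umi``, the number of detected genes
    lies in [``min_genes``, ``max_genes``] and the mitochondrial UMI fraction
    is <= ``max_mito_fraction``.  Reasons are assigned in the fixed order
    ``low_umi``, ``low_genes``, ``high_genes``, ``high_mito``.
    """
    counts = mat.counts
    total = counts.sum(axis=0)
    n_detected = (counts > 0).sum(axis=0)
    mito_rows = np.array(
        [g.startswith(thresholds.mito_gene_prefix) for g in mat.gene_ids], dtype=bool
    )
    mito_total = counts[mito_rows].sum(axis=0) if mito_rows.any() else np.zeros_like(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 1.0)

    fail = {
        "low_umi": total < thresholds.min_umi,
        "low_genes": n_detected < thresholds.min_genes,
        "high_genes": n_detected > thresholds.max_genes,
        "high_mito": mito_frac > thresholds.max_mito_fraction,
    }
    reason = np.full(mat.n_cells, "", dtype=object)
    for code in reversed(QC_REASONS):  # earlier rules overwrite later ones
        reason[fail[code]] = code
    removed = reason != ""

    report = pd.DataFrame(
        {
            "cell_id": np.array(mat.cell_ids, dtype=object)[removed],
            "reason": reason[removed],
            "total_umi": total[removed],
            "n_genes": n_detected[removed],
            "mito_fraction": mito_frac[removed],
        }
    ).reset_index(drop=True)
    if removed.all():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return mat.subset_cells(~removed), report


def normalize_counts(
    mat: ExpressionMatrix,
    scale: float = 10_000.0,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Library-size normalization to ``scale`` counts per cell, then log2.

    ``normalized[g, c] = log2(pseudocount + counts[g, c] * scale / total[c])``.
    Counts are left untouched.
    """
    total = mat.counts.sum(axis=0)
    if np.any(total == 0):
        bad = [mat.cell_ids[i] for i in np.flatnonzero(total == 0)][:5]
        raise ValueError(
            f"cells with zero total counts (run qc_filter first): {bad}"
        )
    normalized = np.log2(pseudocount + mat.counts * (scale / total))
    return replace(mat, normalized=normalized)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene..., one set per line."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: GMT line with fewer than 3 fields")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path, description: str = ".") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def classify_cluster_sharing(
    ann: CellAnnotation,
    threshold: float = 0.60,
) -> pd.DataFrame:
    """Label clusters patient_specific (> ``threshold`` of cells from one
    patient) or shared.

    Returns a table indexed by cluster with columns ``status``,
    ``dominant_patient``, ``dominant_fraction``, ``n_cells``.
    """
    if ann.df.empty:
        raise ValueError("annotation has no cells")
    tab = pd.crosstab(ann.df["cluster"], ann.df["patient"])
    sizes = tab.sum(axis=1)
    dominant = tab.idxmax(axis=1)
    fraction = tab.max(axis=1) / sizes
    status = np.where(fraction > threshold, "patient_specific", "shared")
    return pd.DataFrame(
        {
            "status": status,
            "dominant_patient": dominant,
            "dominant_fraction": fraction,
            "n_cells": sizes,
        },
        index=tab.index,
    )
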