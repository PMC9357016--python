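"""Marker-sum deconvolution of bulk cohorts and TME subtyping.

A cell subtype's abundance in a bulk sample is the sum of log-TPM of its
marker genes; abundances are normalized by the summed abundance of the
patient-shared immune and stromal subtypes.  Signature scores (TLS,
exhaustion) use the same marker-sum rule, cohorts are split at the median,
and samples are partitioned into TME subtypes by k-means on normalized
abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from tmekit.exhaustion import EXHAUSTION_GENES

#: Published 9-gene tertiary-lymphoid-structure signature.
TLS_SIGNATURE_9 = (
    "CD79B", "CD1D", "CCR6", "LAT", "SKAP1", "CETP", "EIF1AY", "RBP5", "PTGDS",
)

#: Published 12-gene chemokine TLS signature.
TLS_SIGNATURE_12 = (
    "CCL2", "CCL3", "CCL4", "CCL5", "CCL8", "CCL18",
    "CCL19", "CCL21", "CXCL9", "CXCL10", "CXCL11", "CXCL13",
)


@dataclass
class BulkCohort:
    """Gene x sample log-TPM table with pass-through sample metadata."""

    expression: pd.DataFrame = field(repr=False)
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.expression.index.duplicated().any():
            dup = self.expression.index[self.expression.index.duplicated()]
            warnings.warn(
                f"summing {len(set(dup))} duplicated gene rows", stacklevel=2
            )
            self.expression = self.expression.groupby(level=0).sum()
        if not np.isfinite(self.expression.to_numpy(dtype=float)).all():
            raise ValueError("non-finite expression values")

    @property
    def samples(self) -> list[str]:
        return self.expression.columns.tolist()

    @classmethod
    def read_tsv(cls, path, metadata_path=None) -> "BulkCohort":
        expr = pd.read_csv(path, sep="\t", index_col=0)
        meta = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(expr, meta)

    def write_tsv(self, path) -> None:
        self.expression.to_csv(path, sep="\t")


@dataclass
class AbundanceMatrix:
    """Subtype x sample scores; ``layer`` is 'absolute' or 'normalized'."""

    scores: pd.DataFrame = field(repr=False)
    layer: str = "absolute"
    missing_genes: dict[str, list[str]] = field(default_factory=dict)


def abundance_scores(
    cohort: BulkCohort, marker_sets: dict[str, list[str]]
) -> AbundanceMatrix:
    """Sum of member-gene log-TPM per subtype and sample."""
    genes = set(cohort.expression.index)
    rows, missing = {}, {}
    for subtype, markers in marker_sets.items():
        present = [g for g in markers if g in genes]
        absent = [g for g in markers if g not in genes]
        if not present:
            raise ValueError(f"subtype {subtype!r}: no marker genes in cohort")
        if absent:
            missing[subtype] = absent
        rows[subtype] = cohort.expression.loc[present].sum(axis=0)
    return AbundanceMatrix(pd.DataFrame(rows).T, "absolute", missing)


def normalize_abundance(
    abundance: AbundanceMatrix, shared_subtypes: list[str] | None = None
) -> AbundanceMatrix:
    """Divide each subtype's score by the summed score of the shared subtypes."""
    if abundance.layer != "absolute":
        raise ValueError("normalize_abundance expects the absolute layer")
    scores = abundance.scores
    shared = list(shared_subtypes) if shared_subtypes is not None else scores.index.tolist()
    if not shared:
        raise ValueError("shared_subtypes is empty")
    unknown = [s for s in shared if s not in scores.index]
    if unknown:
        raise ValueError(f"unknown shared subtypes: {unknown}")
    denom = scores.loc[shared].sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"zero denominator for samples: {zero.index.tolist()[:5]}")
    return AbundanceMatrix(scores.div(denom, axis=1), "normalized", abundance.missing_genes)


def signature_score(cohort: BulkCohort, gene_set: list[str]) -> pd.Series:
    """Marker-sum score of one gene set per sample; missing genes warn."""
    genes = set(cohort.expression.index)
    present = [g for g in gene_set if g in genes]
    if not present:
        raise ValueError("no signature genes present in cohort")
    absent = [g for g in gene_set if g not in genes]
    if absent:
        warnings.warn(f"signature genes missing from cohort: {absent}", stacklevel=2)
    return cohort.expression.loc[present].sum(axis=0)


def median_split(scores: pd.Series, tie: str = "low") -> pd.Series:
    """Label samples 'high' (score > median) or 'low'; median ties go to
    ``tie``."""
    if tie not in ("low", "high"):
        raise ValueError("tie must be 'low' or 'high'")
    med = scores.median()
    labels = np.where(scores > med, "high", "low")
    if tie == "high":
        labels = np.where(scores >= med, "high", "low")
    return pd.Series(labels, index=scores.index, name="group")


def exhaustion_abundance(
    cohort: BulkCohort, genes: list[str] = list(EXHAUSTION_GENES)
) -> pd.Series:
    """Marker-sum over the canonical exhaustion marker set."""
    return signature_score(cohort, genes)


def tme_subtypes(
    abundance: AbundanceMatrix,
    k: int = 7,
    n_init: int = 100,
    seed: int = 0,
    standardize: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means over samples in abundance space.

    Returns per-sample labels TME1..TMEk (numbered by decreasing cluster
    size, ties by centroid order) and the centroid table in abundance units.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = abundance.scores.T.to_numpy(dtype=float)  # samples x subtypes
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds {x.shape[0]} samples")
    fit_x = x
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        fit_x = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(fit_x)
    sizes = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda i: (-sizes[i], i))
    rename = {comp: f"TME{rank + 1}" for rank, comp in enumerate(order)}
    labels = pd.Series(
        [rename[r] for r in raw], index=abundance.scores.columns, name="tme_subtype"
    )
    centroids = pd.DataFrame(
        [x[raw == comp].mean(axis=0) for comp in order],
        index=[f"TME{r + 1}" for r in range(k)],
        columns=abundance.scores.index,
    )
    return labels, centroids


def silhouette_scan(
    abundance: AbundanceMatrix, ks: list[int], seed: int = 0, n_init: int = 10
) -> pd.Series:
    """Diagnostic silhouette score per candidate k (no automatic selection)."""
    x = abundance.scores.T.to_numpy(dtype=float)
    out = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(x)
        out[k] = float(silhouette_score(x, labels))
    return pd.Series(out, name="silhouette")
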