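"""Seeded synthetic single-cell and bulk generators with known ground truth.

Counts are negative-binomial with gene-level log-normal baseline means, the
standard droplet-count model.  Cluster markers are planted as multiplicative
mean shifts (fold change >= 1), ligand-receptor effects as marker-style
shifts of the ligand in a source cluster and the receptor in a target
cluster, and bulk samples as convex mixtures of per-cluster linear-scale
profiles with Gaussian noise on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tmekit.core_io import (
    TISSUES,
    CellAnnotation,
    ExpressionMatrix,
    normalize_counts,
)


@dataclass(frozen=True)
class ClusterSpec:
    """One simulated cluster: size, lineage and label composition."""

    name: str
    lineage: str
    n_cells: int
    tissue_probs: dict[str, float]
    patient_probs: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"cluster {self.name}: n_cells must be >= 1")
        for label, probs in (("tissue", self.tissue_probs), ("patient", self.patient_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"cluster {self.name}: {label} proportions sum to {total}, not 1"
                )
        unknown = set(self.tissue_probs) - set(TISSUES)
        if unknown:
            raise ValueError(f"cluster {self.name}: unknown tissues {sorted(unknown)}")


@dataclass(frozen=True)
class MarkerPlant:
    gene: str
    fold_change: float
    detection_boost: float = 0.0

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValueError("planted fold_change must be >= 1")
        if not 0 <= self.detection_boost <= 1:
            raise ValueError("detection_boost must lie in [0, 1]")


@dataclass(frozen=True)
class LRPlant:
    ligand: str
    receptor: str
    source_cluster: str
    target_cluster: str
    effect: float = 4.0

    def __post_init__(self) -> None:
        if self.effect < 1:
            raise ValueError("planted effect must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int
    clusters: tuple[ClusterSpec, ...]
    marker_spec: dict[str, tuple[MarkerPlant, ...]] = field(default_factory=dict)
    lr_plants: tuple[LRPlant, ...] = ()
    baseline_mean: float = 1.0
    baseline_sigma: float = 0.5
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cluster names")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted parameters recorded for recovery tests."""

    planted_markers: dict[str, dict[str, float]]
    tissue_enrichment: dict[tuple[str, str], float]
    planted_lr: list[tuple[str, str, str, str]]
    bulk_fractions: pd.DataFrame | None = None


def _resolve_gene(gene: str, lookup: dict[str, int]) -> int:
    if gene not in lookup:
        raise ValueError(f"planted gene {gene!r} not among simulated genes")
    return lookup[gene]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    # numpy parameterizes NB by (n, p); mean mu and size r give p = r / (r + mu)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_cells(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CellAnnotation, GroundTruth]:
    """Draw a clustered NB count matrix plus annotations and ground truth.

    Identical config and seed give bit-identical output.  The returned matrix
    already carries the default normalized layer.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    lookup = {g: i for i, g in enumerate(genes)}

    base = rng.lognormal(np.log(config.baseline_mean), config.baseline_sigma, config.n_genes)

    # per-cluster mean vector = baseline, times planted marker and L-R effects
    fc = {c.name: np.ones(config.n_genes) for c in config.clusters}
    planted_markers: dict[str, dict[str, float]] = {}
    boosts: dict[str, list[tuple[int, float]]] = {c.name: [] for c in config.clusters}
    for cluster, plants in config.marker_spec.items():
        if cluster not in fc:
            raise ValueError(f"marker_spec references unknown cluster {cluster!r}")
        planted_markers[cluster] = {}
        for plant in plants:
            gi = _resolve_gene(plant.gene, lookup)
            fc[cluster][gi] *= plant.fold_change
            planted_markers[cluster][plant.gene] = plant.fold_change
            if plant.detection_boost > 0:
                boosts[cluster].append((gi, plant.detection_boost))
    planted_lr: list[tuple[str, str, str, str]] = []
    for lr in config.lr_plants:
        li = _resolve_gene(lr.ligand, lookup)
        ri = _resolve_gene(lr.receptor, lookup)
        if lr.source_cluster not in fc or lr.target_cluster not in fc:
            raise ValueError("lr_plants reference unknown cluster")
        fc[lr.source_cluster][li] *= lr.effect
        fc[lr.target_cluster][ri] *= lr.effect
        planted_lr.append((lr.ligand, lr.receptor, lr.source_cluster, lr.target_cluster))

    blocks, ann_rows = [], []
    offset = 0
    for spec in config.clusters:
        mean = base * fc[spec.name]
        counts = _nb_draw(
            rng, np.broadcast_to(mean[:, None], (config.n_genes, spec.n_cells)), config.dispersion
        )
        for gi, boost in boosts[spec.name]:
            zeros = counts[gi] == 0
            bump = rng.random(spec.n_cells) < boost
            counts[gi, zeros & bump] = 1
        blocks.append(counts)
        tissues = rng.choice(
            list(spec.tissue_probs), size=spec.n_cells, p=list(spec.tissue_probs.values())
        )
        patients = rng.choice(
            list(spec.patient_probs), size=spec.n_cells, p=list(spec.patient_probs.values())
        )
        for j in range(spec.n_cells):
            ann_rows.append(
                {
                    "cell_id": f"cell{offset + j:06d}",
                    "cluster": spec.name,
                    "tissue": tissues[j],
                    "patient": patients[j],
                    "lineage": spec.lineage,
                }
            )
        offset += spec.n_cells

    counts = np.concatenate(blocks, axis=1)
    cell_ids = [r["cell_id"] for r in ann_rows]
    mat = normalize_counts(ExpressionMatrix(genes, cell_ids, counts))
    ann = CellAnnotation(pd.DataFrame(ann_rows))

    truth = GroundTruth(
        planted_markers=planted_markers,
        tissue_enrichment=_expected_ro_e(config),
        planted_lr=planted_lr,
    )
    return mat, ann, truth


def _expected_ro_e(config: SimulationConfig) -> dict[tuple[str, str], float]:
    """Population-level observed/expected ratio implied by the sampling design."""
    total = sum(c.n_cells for c in config.clusters)
    tissue_margin = {t: 0.0 for t in TISSUES}
    for spec in config.clusters:
        for t, p in spec.tissue_probs.items():
            tissue_margin[t] += p * spec.n_cells / total
    out = {}
    for spec in config.clusters:
        for t in TISSUES:
            margin = tissue_margin[t]
            p_ct = spec.tissue_probs.get(t, 0.0)
            out[(spec.name, t)] = p_ct / margin if margin > 0 else np.nan
    return out


def cluster_profiles(mat: ExpressionMatrix, ann: CellAnnotation) -> pd.DataFrame:
    """Per-cluster mean linear-scale expression (library-normalized), genes x clusters."""
    if mat.normalized is None:
        mat = normalize_counts(mat)
    ann = ann.aligned_to(mat)
    linear = np.power(2.0, mat.normalized) - 1.0
    clusters = ann.column("cluster")
    profiles = {
        c: linear[:, clusters == c].mean(axis=1) for c in pd.unique(clusters)
    }
    return pd.DataFrame(profiles, index=mat.gene_ids)


def simulate_bulk(
    signatures: pd.DataFrame,
    fractions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Mix linear-scale cluster profiles into log-scale bulk samples.

    ``signatures`` is genes x clusters (linear scale), ``fractions`` is
    samples x clusters with rows summing to 1.  Sample values are
    ``log2(1 + sum_k f_k * signature_k)`` plus N(0, noise_sd) noise.
    """
    from tmekit.bulk_deconvolution import BulkCohort

    missing = [c for c in fractions.columns if c not in signatures.columns]
    if missing:
        raise ValueError(f"fractions reference unknown clusters: {missing}")
    frac = fractions.to_numpy(dtype=float)
    if frac.size and frac.min() < 0:
        raise ValueError("fractions must be nonnegative")
    row_sums = frac.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-9):
        raise ValueError("fraction rows must sum to 1 within 1e-9")

    rng = np.random.default_rng(seed)
    sig = signatures.loc[:, fractions.columns].to_numpy(dtype=float)
    mixture = sig @ frac.T  # genes x samples, linear scale
    values = np.log2(1.0 + mixture)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.shape)
    expr = pd.DataFrame(values, index=signatures.index, columns=fractions.index.astype(str))
    return BulkCohort(expression=expr)


def simulate_lr_pairs(
    config: SimulationConfig,
    n_decoys: int = 45,
    seed: int | None = None,
):
    """Planted interacting pairs plus decoy pairs with no planted structure."""
    from tmekit.interactions import LRPairSet

    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = config.gene_ids()
    planted_genes = {p for plants in config.marker_spec.values() for p in (x.gene for x in plants)}
    planted_genes |= {g for lr in config.lr_plants for g in (lr.ligand, lr.receptor)}
    free = [g for g in genes if g not in planted_genes]
    if len(free) < 2 * n_decoys:
        raise ValueError(
            f"need {2 * n_decoys} unplanted genes for decoys, have {len(free)}"
        )
    picked = rng.choice(free, size=2 * n_decoys, replace=False)
    rows = [
        {"ligand": lr.ligand, "receptor": lr.receptor, "source": "planted"}
        for lr in config.lr_plants
    ]
    rows += [
        {"ligand": picked[2 * i], "receptor": picked[2 * i + 1], "source": "decoy"}
        for i in range(n_decoys)
    ]
    return LRPairSet(pd.DataFrame(rows))
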