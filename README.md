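# tmekit

Analysis toolkit for single-cell tumor-microenvironment studies, built
around seven statistical stages that are exercised end-to-end on a seeded
synthetic data generator:

- **core_io** — MatrixMarket/TSV readers and writers, per-cell QC filtering
  (UMI, gene-count and mitochondrial-fraction thresholds), library-size
  log2 normalization, and patient-shared vs patient-specific cluster
  classification.
- **synthetic_data** — negative-binomial clustered count matrices with
  planted markers, tissue/patient composition, ligand-receptor axes, and
  bulk pseudo-mixtures — all with recorded ground truth.
- **markers** — three-criterion marker calling (Wilcoxon rank-sum with
  Bonferroni over all genes, linear-scale fold change, detection-percentage
  gap) and group-contrast signatures.
- **tissue_preference** — observed/expected enrichment ratios per
  (cluster, tissue) with 2x2 chi-squared significance.
- **cluster_similarity** — weighted shared-marker fold-change scoring and
  ridge-logistic classifier transfer between datasets.
- **exhaustion** — k-means subclustering of cytotoxic T cells on effector
  molecules, ordering by effector loss, exhausted / pre-exhausted flagging
  by marker-set overlap.
- **interactions** — ligand-receptor interaction intensities
  (product of cluster means), cluster-tag permutation testing with
  Bonferroni correction, eligibility and expression floors, communication
  networks, and ligand-pathway Spearman bipartite networks.
- **bulk_deconvolution** — marker-sum subtype abundances in bulk cohorts,
  shared-subtype normalization, TLS and exhaustion signature scores with
  median splits, and k-means TME subtyping.
- **robustness** — clustering-stability NMI under down-sampling and
  leave-one-patient-out protocols with a pluggable clustering callback.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(permutation calibration and power, oracle equivalences, recovery
simulations, end-to-end determinism).

## CLI

```sh
tmekit run --seed 1 --out-dir out            # full pipeline on the synthetic fixture
tmekit simulate --out-dir fix --seed 1       # write an MTX/TSV fixture
tmekit qc fix                                # QC report
tmekit markers fix --out markers.tsv         # cluster markers
tmekit preference fix                        # tissue-preference table
tmekit interact fix --pairs fix/lr_pairs.csv --n-perm 200 --seed 7
tmekit decon --cohort bulk.tsv --marker-sets sets.gmt --k 7
tmekit robustness fix --k 6
```

`tmekit run` accepts a YAML config (`--config`) whose blocks mirror each
stage's parameters; unknown keys are rejected, and all stage defaults equal
the published protocol values (QC 200 UMIs / 200–8000 genes / 10% mito;
markers adjusted p < 0.01, 2-fold, 20% detection gap; 1000 permutations
with intensity > 1 and adjusted p < 0.01; k = 5 exhaustion states;
down-sampling 1/2–1/5 with 100 replicates; k = 7 TME subtypes). Every run
writes a `manifest.json` recording the config hash and seed.

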