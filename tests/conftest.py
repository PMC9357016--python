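import numpy as np
import pandas as pd
import pytest

from tmekit import synthetic_data as sd
from tmekit.cli_config import default_simulation

PT_ONLY = {"PT": 1.0}
ONE_PATIENT = {"P1": 1.0}


@pytest.fixture(scope="session")
def small_dataset():
    """Default six-cluster fixture at reduced size, with ground truth."""
    cfg = default_simulation(seed=1, n_genes=300, cells_per_cluster=120)
    mat, ann, truth = sd.simulate_cells(cfg)
    return cfg, mat, ann, truth


@pytest.fixture(scope="session")
def marker_dataset():
    """Three clusters x 500 cells with ten planted FC-4 markers each."""
    clusters = tuple(
        sd.ClusterSpec(f"C{i}", "T/NK", 500, PT_ONLY, ONE_PATIENT) for i in range(3)
    )
    marker_spec = {
        f"C{i}": tuple(sd.MarkerPlant(f"G{(i * 10 + j):04d}", 4.0) for j in range(10))
        for i in range(3)
    }
    # moderate, weakly dispersed baseline keeps detection off saturation so
    # an FC-4 plant yields a clear detection-percentage gap
    cfg = sd.SimulationConfig(
        n_genes=300, clusters=clusters, marker_spec=marker_spec,
        baseline_mean=0.8, baseline_sigma=0.25, seed=7,
    )
    mat, ann, truth = sd.simulate_cells(cfg)
    return cfg, mat, ann, truth


@pytest.fixture(scope="session")
def separable_dataset():
    """Three well-separated clusters (ten FC-8 markers in 40 genes)."""
    clusters = tuple(
        sd.ClusterSpec(f"K{i}", "T/NK", 200, PT_ONLY, {f"P{i % 3 + 1}": 1.0})
        for i in range(3)
    )
    marker_spec = {
        f"K{i}": tuple(sd.MarkerPlant(f"G{(i * 10 + j):04d}", 8.0) for j in range(10))
        for i in range(3)
    }
    cfg = sd.SimulationConfig(
        n_genes=40, clusters=clusters, marker_spec=marker_spec, seed=9
    )
    mat, ann, truth = sd.simulate_cells(cfg)
    return cfg, mat, ann, truth


def make_gradient_dataset(seed: int):
    """Five-state effector gradient with a shared bottom-two signature."""
    eff = [f"G{j:04d}" for j in range(10)]
    sig = [f"G{(20 + j):04d}" for j in range(10)]
    ladder = [81, 27, 9, 3, 1]
    clusters = tuple(
        sd.ClusterSpec(f"S{i + 1}", "T/NK", 150, PT_ONLY, ONE_PATIENT) for i in range(5)
    )
    marker_spec = {
        f"S{i + 1}": tuple(sd.MarkerPlant(g, ladder[i]) for g in eff) for i in range(5)
    }
    for s in ("S4", "S5"):
        marker_spec[s] = marker_spec[s] + tuple(sd.MarkerPlant(g, 6.0) for g in sig)
    cfg = sd.SimulationConfig(
        n_genes=1000,
        clusters=clusters,
        marker_spec=marker_spec,
        baseline_mean=2.0,
        dispersion=50.0,
        seed=seed,
    )
    mat, ann, truth = sd.simulate_cells(cfg)
    return cfg, mat, ann, truth, eff


@pytest.fixture(scope="session")
def gradient_dataset():
    return make_gradient_dataset(seed=400)


@pytest.fixture(scope="session")
def bulk_mixture():
    """Eight cluster profiles mixed into 50 Dirichlet bulk samples."""
    clusters = tuple(
        sd.ClusterSpec(f"C{i}", "T/NK", 200, PT_ONLY, ONE_PATIENT) for i in range(8)
    )
    marker_spec = {
        f"C{i}": tuple(sd.MarkerPlant(f"G{(i * 10 + j):04d}", 4.0) for j in range(10))
        for i in range(8)
    }
    cfg = sd.SimulationConfig(
        n_genes=120, clusters=clusters, marker_spec=marker_spec, seed=42
    )
    mat, ann, _ = sd.simulate_cells(cfg)
    profiles = sd.cluster_profiles(mat, ann)
    rng = np.random.default_rng(1)
    fractions = pd.DataFrame(
        rng.dirichlet(np.ones(8), size=50),
        index=[f"S{i:02d}" for i in range(50)],
        columns=profiles.columns,
    )
    cohort = sd.simulate_bulk(profiles, fractions, noise_sd=0.1, seed=2)
    marker_sets = {
        c: [f"G{(i * 10 + j):04d}" for j in range(10)]
        for i, c in enumerate(profiles.columns)
    }
    return profiles, fractions, cohort, marker_sets
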