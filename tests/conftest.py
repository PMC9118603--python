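import warnings

import numpy as np
import pytest

import mlsae

warnings.filterwarnings("ignore", category=FutureWarning)

#: Component set of the default (stunting-like) model.
STUNTING_COMPONENTS = (
    "RES_DIST_AGE",
    "RES_DIST_SEX",
    "AGE_DIST",
    "SP_DIST",
    "WN_DIV",
    "WN_DIST",
)


@pytest.fixture(scope="session")
def full_lattice() -> mlsae.DomainLattice:
    """64 districts / 8 divisions / 2x5x2 demography: 1280 domains."""
    return mlsae.example_lattice(64, 8)


@pytest.fixture(scope="session")
def full_graph(full_lattice) -> mlsae.AdjacencyGraph:
    return mlsae.grid_adjacency(full_lattice.districts)


@pytest.fixture(scope="session")
def small_lattice() -> mlsae.DomainLattice:
    """12 districts / 2 divisions / 2 ages: 96 domains."""
    return mlsae.example_lattice(12, 2, n_ages=2)


@pytest.fixture(scope="session")
def small_graph(small_lattice) -> mlsae.AdjacencyGraph:
    return mlsae.grid_adjacency(small_lattice.districts)


@pytest.fixture(scope="session")
def small_fit(small_lattice, small_graph):
    """One fitted pipeline run on synthetic data (shared, read-only)."""
    params = mlsae.GenerativeParams(seed=5)
    truth = mlsae.draw_truth(
        small_lattice, small_graph, params, components=STUNTING_COMPONENTS
    )
    table = mlsae.simulate_direct(truth, small_lattice, params)
    config = mlsae.SamplerConfig(n_chains=2, n_iter=1200, n_burn=600, seed=3)
    fit = mlsae.fit_model(table, small_lattice, small_graph, STUNTING_COMPONENTS, config)
    weights = mlsae.population_weights(small_lattice, seed=1)
    return {"fit": fit, "table": table, "truth": truth, "weights": weights}


def dense_Z(component, n_domains: int) -> np.ndarray:
    """Explicit dense incidence matrix built independently of the
    component's own fast paths."""
    Z = np.zeros((n_domains, component.q))
    for row, col in enumerate(component.effect_index):
        Z[row, col] = 1.0
    return Z
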