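import numpy as np
import pytest

from kneeload.graph import ServeGraph, build_graph, complete_edge_index
from kneeload.preprocess import assemble_matrices
from kneeload.synthetic import SimulationConfig, simulate_dataset, simulate_trial


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_participants=3, trials_per_participant=4, seed=11)


@pytest.fixture(scope="session")
def small_trials(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def one_trial(small_config):
    return simulate_trial(small_config, 0, 0)


@pytest.fixture(scope="session")
def one_normalized(one_trial):
    return assemble_matrices(one_trial)


@pytest.fixture(scope="session")
def one_graph(one_normalized) -> ServeGraph:
    return build_graph(one_normalized)


@pytest.fixture
def random_graph_factory():
    """Small random graphs for dense-oracle checks."""

    def make(rng: np.random.Generator, n_nodes: int, n_features: int = 4,
             p_edge: float = 0.5) -> ServeGraph:
        mask = rng.uniform(size=(n_nodes, n_nodes)) < p_edge
        mask |= mask.T  # symmetric as a set of ordered pairs
        np.fill_diagonal(mask, False)
        src, dst = np.nonzero(mask)
        if src.size == 0:
            src, dst = np.array([0]), np.array([min(1, n_nodes - 1)])
        return ServeGraph(
            node_features=rng.normal(size=(n_nodes, n_features)),
            edge_index=np.stack([src, dst]),
            edge_attr=np.ones(src.size),
            target=rng.normal(size=n_nodes),
        )

    return make


@pytest.fixture
def complete_graph_factory():
    def make(rng: np.random.Generator, n_nodes: int, n_features: int = 4) -> ServeGraph:
        ei = complete_edge_index(n_nodes, self_loops=True)
        return ServeGraph(
            node_features=rng.normal(size=(n_nodes, n_features)),
            edge_index=ei,
            edge_attr=np.ones(ei.shape[1]),
            target=rng.normal(size=n_nodes),
        )

    return make
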