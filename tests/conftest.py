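import numpy as np
import pytest
from hypothesis import settings

from morbnet.catalog import N_DISEASES
from morbnet.ising import IsingNetwork
from morbnet.synthetic import elsi_like_truth, generate_cohort

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def network_from_edges(n_nodes: int, edges: dict[tuple[int, int], float],
                       thresholds: np.ndarray | None = None,
                       labels: list[str] | None = None) -> IsingNetwork:
    W = np.zeros((n_nodes, n_nodes))
    for (i, j), w in edges.items():
        W[i, j] = W[j, i] = w
    return IsingNetwork(
        nodes=labels or [f"v{i}" for i in range(n_nodes)],
        weights=W,
        thresholds=np.zeros(n_nodes) if thresholds is None else thresholds,
        gamma=0.25,
        n=1000,
    )


@pytest.fixture(scope="session")
def two_clique_network() -> IsingNetwork:
    """Two unit-weight triangles joined by one bridge edge."""
    edges = {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0,
             (3, 4): 1.0, (3, 5): 1.0, (4, 5): 1.0, (2, 3): 1.0}
    return network_from_edges(6, edges)


@pytest.fixture(scope="session")
def path_network() -> IsingNetwork:
    """3-node unit-weight path a - b - c."""
    return network_from_edges(3, {(0, 1): 1.0, (1, 2): 1.0}, labels=["a", "b", "c"])


@pytest.fixture(scope="session")
def elsi_truth():
    return elsi_like_truth(seed=0)


@pytest.fixture(scope="session")
def small_cohort(elsi_truth):
    """A modest synthetic cohort shared by preprocess/regression tests."""
    return generate_cohort(elsi_truth, 4000, seed=99)


@pytest.fixture(scope="session")
def observed_cohort(elsi_truth):
    """A cohort generated without any missingness applied."""
    return generate_cohort(elsi_truth, 4000, seed=21, apply_missing=False)


@pytest.fixture(scope="session")
def complete_cohort(small_cohort):
    from morbnet.preprocess import complete_cases

    return complete_cases(small_cohort)


def planted_graph(p: int = 10, seed: int = 0):
    """A sparse planted coupling matrix with moderate-to-strong edges."""
    rng = np.random.default_rng(seed)
    pairs = [(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (7, 8), (8, 9), (0, 4), (3, 7)]
    W = np.zeros((p, p))
    for i, j in pairs:
        w = rng.uniform(0.8, 1.5)
        W[i, j] = W[j, i] = w
    return W, set(pairs)


assert N_DISEASES == 19
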