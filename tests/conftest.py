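import numpy as np
import pytest

from spatialnb import synthetic
from spatialnb.weights import WeightMatrix, queen_contiguity


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared across read-only tests."""
    params = synthetic.TrueParams(
        beta=(2.5, -0.2, 0.15), n_regions=8, clusters_per_region=8, seed=11
    )
    table, W, truth = synthetic.simulate_study(params)
    return params, table, W, truth


@pytest.fixture()
def ring5():
    """5-node cycle graph weight matrix (binary)."""
    edges = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 1)]
    return queen_contiguity(edge_list=edges)


def random_weight_matrix(rng, n):
    """Random symmetric non-negative weights, zero diagonal, for oracles."""
    w = rng.uniform(size=(n, n)) * (rng.uniform(size=(n, n)) < 0.5)
    w = np.triu(w, 1)
    w = w + w.T
    if w.sum() == 0:
        w[0, 1] = w[1, 0] = 1.0
    return WeightMatrix(w, scheme="queen")
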