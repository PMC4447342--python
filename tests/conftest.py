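import numpy as np
import pandas as pd
import pytest

from paracrine.matrix import ExpressionMatrix
from paracrine.network import Cpdag
from paracrine.simulate import make_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced planted-truth benchmark shared by read-only tests."""
    return make_benchmark(
        n_network=40,
        n_secreted=12,
        n_regulators=3,
        n_responsive=15,
        n_null=10,
        n_samples=15,
        n_controls=4,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_matrix(values, genes=None, samples=None, role=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1:02d}" for i in range(values.shape[0])]
    samples = samples or [f"s{i + 1:02d}" for i in range(values.shape[1])]
    roles = pd.Series(role, index=samples) if role is not None else None
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), roles)


def cpdag_from_edges(nodes, directed=(), undirected=()):
    g = Cpdag(sorted(nodes))
    for (u, v) in directed:
        g.amat[g.index(u), g.index(v)] = 1
    for (u, v) in undirected:
        g.amat[g.index(u), g.index(v)] = 1
        g.amat[g.index(v), g.index(u)] = 1
    return g
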