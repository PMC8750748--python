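import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rxnuq.chemio import FeatureConfig, MolecularGraph, ReactionRecord
from rxnuq.nnet import ModelDims, ModelParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: molecules covering aromatics, heteroatoms, rings, stereo-free chains
SMILES_POOL = [
    "c1ccccc1", "c1ccncc1", "CCO", "CC(=O)O", "CCN", "C1CCOC1",
    "Clc1ccccc1", "OCc1ccccc1", "CC#N", "CC(C)O",
]


@pytest.fixture(scope="session")
def feature_config():
    return FeatureConfig.from_smiles(SMILES_POOL)


@pytest.fixture(scope="session")
def tiny_dims():
    # abstract feature lengths: graphs built directly from random arrays
    return ModelDims(p=5, q=3, node_dim=4, edge_hidden=3, graph_dim=6,
                     fnn_hidden=5, dropout=0.1)


@pytest.fixture
def tiny_params(tiny_dims):
    return ModelParams.init(tiny_dims, 0)


def random_graph(rng, p=5, q=3, max_nodes=5):
    """A random featurized graph (not chemically meaningful) for numeric
    tests: random node/edge features over a random connected-ish edge set."""
    n = int(rng.integers(1, max_nodes + 1))
    X = rng.normal(size=(n, p))
    edges = {}
    if n > 1:
        for j in range(1, n):  # spanning-tree edges keep the graph connected
            k = int(rng.integers(0, j))
            edges[(min(j, k), max(j, k))] = rng.normal(size=q)
        for _ in range(int(rng.integers(0, n))):
            j, k = rng.choice(n, size=2, replace=False)
            edges[(min(j, k), max(j, k))] = rng.normal(size=q)
    return MolecularGraph(X, edges)


def random_record(rng, p=5, q=3, m_max=3, yield_percent=50.0):
    m = int(rng.integers(1, m_max + 1))
    return ReactionRecord(
        reactants=[random_graph(rng, p, q) for _ in range(m)],
        product=random_graph(rng, p, q),
        yield_percent=yield_percent,
    )
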