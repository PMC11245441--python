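import numpy as np
import pytest
from hypothesis import settings

import mlbundle as mb

settings.register_profile("ci", derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One synthetic network + feature matrix + fitted model (n=80, m=160)."""
    cfg = mb.SynthConfig(phi=0.8, n=80, m=160, sigma=0.2, n_extra_edges=5,
                         seed=7)
    rng = cfg.rng()
    net = mb.assign_edge_polarities(mb.grow_structural_network(cfg, rng), rng)
    S = mb.synthesize_feature_matrix(net, cfg, rng)
    model = mb.MultiLayerBundling(n_layers=5, n_regimes=10).fit(S)
    return cfg, net, S, model


def block_affinity(block_sizes, within=1.0, between=0.0):
    """Block-structured affinity with zero diagonal."""
    n = sum(block_sizes)
    A = np.full((n, n), between, dtype=float)
    start = 0
    for s in block_sizes:
        A[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(A, 0.0)
    return A


@pytest.fixture
def make_block_affinity():
    return block_affinity


def random_regimes(rng, n, counts):
    """A stack of ClusteringRegime objects with random labels.

    Each regime's labels are drawn uniformly; cluster counts follow
    ``counts`` in prominence order (labels may use fewer values by chance,
    which the bundling math tolerates).
    """
    regimes = []
    for rank, c in enumerate(counts, start=1):
        labels = rng.integers(c, size=n)
        regimes.append(
            mb.ClusteringRegime(rank=rank, n_clusters=c, labels=labels)
        )
    return regimes
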