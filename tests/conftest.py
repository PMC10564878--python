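import numpy as np
import pytest

import biasaudit as ba


def random_layered_dag(rng: np.random.Generator, layer_sizes=None) -> ba.LayeredDAG:
    """Random strictly layered DAG; every non-input node gets >= 1 parent."""
    if layer_sizes is None:
        n_layers = rng.integers(2, 4)
        layer_sizes = [int(rng.integers(2, 6)) for _ in range(n_layers)]
    nodes, edges = {}, []
    prev = []
    for li, size in enumerate(layer_sizes):
        cur = [f"L{li}N{j}" for j in range(size)]
        for n in cur:
            nodes[n] = li
        if prev:
            for n in cur:
                k = int(rng.integers(1, len(prev) + 1))
                parents = rng.choice(prev, size=k, replace=False)
                edges.extend((p, n) for p in parents)
        prev = cur
    return ba.LayeredDAG(nodes=nodes, edges=tuple(edges))


@pytest.fixture
def chain_dag():
    return ba.LayeredDAG(nodes={"a": 0, "b": 1, "c": 2}, edges=(("a", "b"), ("b", "c")))


@pytest.fixture
def diamond_dag():
    return ba.LayeredDAG(
        nodes={"a": 0, "b": 1, "c": 1, "d": 2},
        edges=(("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")),
    )


@pytest.fixture(scope="session")
def small_spec():
    """A fast-to-train benchmark: 30 genes, two pathway layers, 200 samples."""
    return ba.SyntheticSpec(n_genes=30, pathway_layer_sizes=(12, 6), n_samples=200,
                            n_planted=8, seed=7)


@pytest.fixture(scope="session")
def small_dag(small_spec):
    return ba.make_synthetic_dag(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_dag):
    return ba.threshold_expand(ba.make_synthetic_cohort(small_dag, small_spec))


@pytest.fixture(scope="session")
def fast_config():
    return ba.NetworkConfig(epochs=60, patience=10)


@pytest.fixture(scope="session")
def trained_small_net(small_dag, small_cohort, fast_config):
    split = ba.make_split(small_cohort, split_seed=3)
    net = ba.init_network(small_dag, fast_config.with_seed(11))
    return ba.train(net, small_cohort, split), split
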