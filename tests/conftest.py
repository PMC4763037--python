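import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hrgnet import DirectedNetwork, build_ensemble

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_directed_network(genes, p, rng):
    regs = [(u, v) for u in genes for v in genes if u != v and rng.random() < p]
    return DirectedNetwork(genes, regs)


def random_ensemble(n_genes, ng, p, rng):
    """Erdos-Renyi-like bootstrap ensemble used across the annealing tests."""
    genes = [f"g{i}" for i in range(n_genes)]
    return build_ensemble([random_directed_network(genes, p, rng) for _ in range(ng)])


@pytest.fixture
def toy_networks():
    """The three-gene worked example: G1 = {a-b, b-c}, G2 = {a-b} (as directed input)."""
    return [
        DirectedNetwork("abc", [("a", "b"), ("b", "c")]),
        DirectedNetwork("abc", [("a", "b")]),
    ]


@pytest.fixture
def toy_ensemble(toy_networks):
    return build_ensemble(toy_networks)


@pytest.fixture
def rng():
    return np.random.default_rng(20160223)
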