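import numpy as np
import pytest

from ssame import AlterationMatrix, GeneNetwork, SimulationConfig, simulate_study
from ssame.simulate import generate_test_network


def make_matrix(genes, samples, altered_pairs):
    """Binary matrix from a list of (gene, sample) pairs."""
    values = np.zeros((len(genes), len(samples)), dtype=np.uint8)
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: i for i, s in enumerate(samples)}
    for g, s in altered_pairs:
        values[gi[g], si[s]] = 1
    return AlterationMatrix(genes, samples, values)


def random_instance(rng, max_genes=6, max_samples=30, min_genes=2):
    """Random (V, matrix) instance for oracle-agreement property tests."""
    k = int(rng.integers(min_genes, max_genes + 1))
    n_samples = int(rng.integers(1, max_samples + 1))
    genes = [f"g{i}" for i in range(k)]
    samples = [f"s{j}" for j in range(n_samples)]
    values = (rng.random((k, n_samples)) < rng.uniform(0.05, 0.6)).astype(np.uint8)
    return genes, AlterationMatrix(genes, samples, values)


@pytest.fixture
def toy_net():
    """Small connected network: a hub plus a cycle."""
    net = GeneNetwork()
    edges = [
        ("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("C", "D"),
        ("D", "E"), ("E", "F"), ("F", "A"), ("F", "G"), ("G", "B"),
    ]
    for u, v in edges:
        net.add_edge(u, v)
    return net


@pytest.fixture
def toy_mat(toy_net):
    genes = toy_net.nodes
    samples = [f"s{i}" for i in range(6)]
    # A, B, C mutually exclusive in 2 samples each; D noisy
    pairs = [
        ("A", "s0"), ("A", "s1"),
        ("B", "s2"), ("B", "s3"),
        ("C", "s4"), ("C", "s5"),
        ("D", "s0"), ("D", "s3"),
    ]
    return make_matrix(genes, samples, pairs)


@pytest.fixture(scope="session")
def toy_study():
    """Small simulated study reused by slower end-to-end tests."""
    rng = np.random.default_rng(11)
    net = generate_test_network(60, 4.0, rng)
    cfg = SimulationConfig(n_samples=40, max_target_edges=8, rng_seed=12)
    return simulate_study(cfg, net)
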