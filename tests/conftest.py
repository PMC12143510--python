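import networkx as nx
import numpy as np
import pytest

from eccdriver.synth import PlantSpec, generate_preset, make_annotation, make_eccdna


@pytest.fixture
def toy_graph():
    """The worked example: S-u1, S-d1, u1-d2, u1-d3 with DEGs {d1,d2,d3}."""
    g = nx.Graph([("S", "u1"), ("S", "d1"), ("u1", "d2"), ("u1", "d3")])
    return g, {"d1", "d2", "d3"}


@pytest.fixture(scope="session")
def small_preset():
    return generate_preset("small", seed=11)


def random_graph_case(seed, max_nodes=50):
    """A random graph with random DEG labels and a random candidate subset."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_nodes + 1))
    p = float(rng.uniform(0.05, 0.4))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
    nodes = sorted(g.nodes)
    degs = {v for v in nodes if rng.random() < 0.3}
    k = int(rng.integers(1, max(2, n // 2)))
    edg = set(rng.choice(nodes, size=k, replace=False))
    return g, degs, edg


def random_containment_fixture(seed):
    """A small annotation plus planted circles for mode-subset checks."""
    ann = make_annotation(n_genes=12, chrom_length=250_000, seed=seed)
    spec = PlantSpec(
        n_planted_eeg=2, n_planted_erg=2, n_decoy_partial=2, n_background=3,
        seed=seed,
    )
    ecc, truth = make_eccdna(ann, spec)
    return ann, ecc, truth
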