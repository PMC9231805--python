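import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from occnet.abundance import AbundanceTable
from occnet.network import CooccurrenceNetwork

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def as_network(graph: nx.Graph, weight: float = 1.0) -> CooccurrenceNetwork:
    """Wrap an unweighted nx graph as an all-positive signed network."""
    g = nx.Graph()
    g.add_nodes_from(str(n) for n in graph.nodes)
    for u, v in graph.edges:
        g.add_edge(str(u), str(v), raw_weight=weight)
    return CooccurrenceNetwork(g)


def random_signed_network(
    n: int, p: float, seed: int, p_negative: float = 0.5
) -> CooccurrenceNetwork:
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=seed)
    out = nx.Graph()
    out.add_nodes_from(str(v) for v in g.nodes)
    for u, v in g.edges:
        w = 1.0 - rng.random()
        if rng.random() < p_negative:
            w = -w
        out.add_edge(str(u), str(v), raw_weight=w)
    return CooccurrenceNetwork(out)


def block_abundance_table(
    seed: int,
    n_blocks: int = 3,
    block_size: int = 30,
    n_samples: int = 60,
    within_correlation: float = 0.9,
) -> AbundanceTable:
    """Taxa in the same block share a latent log profile (corr ~0.9)."""
    rng = np.random.default_rng(seed)
    a = np.sqrt(within_correlation)
    rows = []
    for _ in range(n_blocks):
        z = rng.normal(size=n_samples)
        for _ in range(block_size):
            eps = rng.normal(size=n_samples)
            rows.append(np.exp(2.0 * (a * z + np.sqrt(1 - a * a) * eps)))
    n = n_blocks * block_size
    return AbundanceTable(
        taxon_ids=[f"taxon_{i:03d}" for i in range(n)],
        sample_ids=[f"s{j:02d}" for j in range(n_samples)],
        counts=np.array(rows),
    )


@pytest.fixture
def tiny_table() -> AbundanceTable:
    return AbundanceTable(
        taxon_ids=["otu1", "otu2", "otu3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        counts=np.array(
            [[10.0, 4.0, 6.0, 2.0], [1.0, 9.0, 3.0, 8.0], [5.0, 5.0, 5.0, 5.0]]
        ),
        taxonomy=[
            "Bacteria;Proteobacteria;Alpha",
            "Bacteria;Cyanobacteria;Cyanophyceae;Nostocales;Nostocaceae;Nostoc",
            "Bacteria;Firmicutes",
        ],
    )
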