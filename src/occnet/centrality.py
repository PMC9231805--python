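"""Potential key-taxa metrics: four node centralities with rank columns.

Degree centrality measures popularity, closeness measures how fast a
node can reach (influence) the rest of the network, betweenness flags
bridge nodes, and PageRank ranks nodes by the structure of incoming
links (undirected edges count as reciprocal). High-centrality taxa are
candidate keystone taxa.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .network import CooccurrenceNetwork

__all__ = ["centralities"]

METRICS = ("degree_centrality", "closeness", "betweenness", "pagerank")

#: above this size betweenness switches to sampled estimation
EXACT_BETWEENNESS_MAX_NODES = 5000
BETWEENNESS_SAMPLE_K = 1000


def centralities(
    net: CooccurrenceNetwork, damping: float = 0.85, seed: int | None = None
) -> pd.DataFrame:
    """Per-node centrality table on the unweighted graph.

    Columns: the four metrics plus ``rank_<metric>`` (1 = most central;
    ties broken by taxon id). Closeness uses the within-component
    convention scaled by component size, so it is well defined on
    disconnected graphs. Betweenness is normalized and exact up to
    5,000 nodes (k=1000 source samples above that).
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    g = net.unsigned_graph()
    n = g.number_of_nodes()
    if n > EXACT_BETWEENNESS_MAX_NODES:
        betweenness = nx.betweenness_centrality(
            g, k=BETWEENNESS_SAMPLE_K, normalized=True, seed=seed
        )
    else:
        betweenness = nx.betweenness_centrality(g, normalized=True)
    df = pd.DataFrame(
        {
            "degree_centrality": nx.degree_centrality(g),
            "closeness": nx.closeness_centrality(g),
            "betweenness": betweenness,
            "pagerank": nx.pagerank(g, alpha=damping),
        }
    )
    df.index.name = "taxon_id"
    df = df.sort_index()
    for metric in METRICS:
        order = df[metric].rank(ascending=False, method="first")
        df[f"rank_{metric}"] = order.astype(int)
    return df
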