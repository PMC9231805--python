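"""Community (subnetwork) analysis: Louvain partitions and per-group metrics.

The network can be split either by the Louvain modularity-maximizing
algorithm or by externally supplied groups (e.g. HDBSCAN clusters from
the embedding module). Each group's induced subgraph is characterized
with the same metrics used globally, plus its phylum composition when
taxonomy is available (phylum = second ";"-field of the lineage, "NA"
when unassigned).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import TaxonomyRecord
from .network import CooccurrenceNetwork

__all__ = ["louvain_partition", "subnetwork_metrics", "SubnetworkReport"]

NOISE_LABEL = "noise"


def louvain_partition_graph(
    g: nx.Graph, seed: int | None = None, weight: str | None = None
) -> dict:
    """Louvain on a bare networkx graph; helper shared with percolation."""
    if g.number_of_edges() == 0:
        warnings.warn(
            "edgeless graph: every node is its own community", stacklevel=2
        )
        return {node: i for i, node in enumerate(g.nodes)}
    communities = nx.community.louvain_communities(g, weight=weight, seed=seed)
    return {node: i for i, nodes in enumerate(communities) for node in nodes}


def louvain_partition(
    net: CooccurrenceNetwork, seed: int | None = None, weighted: bool = False
) -> dict:
    """Louvain communities of the co-occurrence network.

    By default runs on the binary (unweighted) edge set; ``weighted=True``
    uses the normalized weights instead. Deterministic given ``seed``.
    """
    g = net.graph if weighted else net.unsigned_graph()
    return louvain_partition_graph(
        g, seed=seed, weight="norm_weight" if weighted else None
    )


class SubnetworkReport(pd.DataFrame):
    """Per-group metric table; plain DataFrame with a fixed column contract."""

    @property
    def _constructor(self):
        return SubnetworkReport


def _group_metrics(sub: nx.Graph) -> dict:
    n = sub.number_of_nodes()
    m = sub.number_of_edges()
    out = {
        "n_nodes": n,
        "n_edges": m,
        "density": nx.density(sub) if n > 1 else 0.0,
        "avg_degree": 2 * m / n if n else 0.0,
        "clustering_coefficient": nx.average_clustering(sub) if n else np.nan,
    }
    if m == 0:
        out["diameter"] = np.nan
        out["avg_shortest_path"] = np.nan
    else:
        if nx.is_connected(sub):
            giant = sub
        else:
            giant = sub.subgraph(max(nx.connected_components(sub), key=len))
        out["diameter"] = float(nx.diameter(giant))
        out["avg_shortest_path"] = nx.average_shortest_path_length(giant)
    return out


def subnetwork_metrics(
    net: CooccurrenceNetwork,
    partition: dict,
    taxonomy: dict | None = None,
    partition_source: str = "custom",
) -> SubnetworkReport:
    """Induced-subgraph metrics and phylum composition per group.

    ``partition`` maps every node to a group label; HDBSCAN's -1 becomes
    the group "noise". Groups of a single node are flagged noise-like.
    ``taxonomy`` maps node -> ";"-delimited lineage; phylum counts land
    in the ``phylum_counts`` column as a dict.
    """
    nodes = set(net.graph.nodes)
    missing = nodes - set(partition)
    if missing:
        raise ValueError(f"partition missing nodes: {sorted(missing)[:5]}")
    groups: dict = {}
    for node in nodes:
        label = partition[node]
        label = NOISE_LABEL if label == -1 else label
        groups.setdefault(label, []).append(node)

    rows = []
    for label in sorted(groups, key=str):
        members = groups[label]
        sub = net.unsigned_graph().subgraph(members)
        row = {"group_id": label, "partition_source": partition_source}
        row.update(_group_metrics(sub))
        row["noise_like"] = label == NOISE_LABEL or len(members) == 1
        if taxonomy is not None:
            phyla = [
                TaxonomyRecord(taxonomy.get(node, "")).phylum for node in members
            ]
            counts: dict[str, int] = {}
            for p in phyla:
                counts[p] = counts.get(p, 0) + 1
            row["phylum_counts"] = counts
        rows.append(row)
    return SubnetworkReport(pd.DataFrame(rows))
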