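"""Signed co-occurrence networks from correlation matrices.

Each taxon is a node; an included correlation rho_ij becomes an
undirected edge carrying both the raw weight (in [-1, 1]) and a
normalized weight (raw + 1) / 2 in [0, 1], so that analyses that cannot
handle negative weights can run on the same graph. Downstream
topological metrics operate on the unweighted edge set; raw signs feed
the balance and sign-ratio analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .sparcc import CorrelationResult

__all__ = [
    "CooccurrenceNetwork",
    "build_network",
    "normalize_weight",
    "export_network",
    "load_network",
]


def normalize_weight(raw: float) -> float:
    """Map a correlation in [-1, 1] affinely onto [0, 1].

    Strictly increasing, so sign information survives as norm > 0.5
    iff raw > 0.
    """
    if not -1.0 <= raw <= 1.0:
        raise ValueError(f"raw weight {raw} outside [-1, 1]")
    return (raw + 1.0) / 2.0


@dataclass
class CooccurrenceNetwork:
    """Undirected signed weighted graph over taxa.

    Thin wrapper around a :class:`networkx.Graph` whose edges carry
    ``raw_weight`` and ``norm_weight`` attributes and whose nodes may
    carry ``taxonomy``, ``hdbscan_label`` and ``louvain_label``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:3]}")
        for u, v, d in self.graph.edges(data=True):
            raw = d.get("raw_weight")
            if raw is None:
                raise ValueError(f"edge ({u}, {v}) missing raw_weight")
            d["norm_weight"] = normalize_weight(raw)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def raw_weights(self) -> dict[tuple[str, str], float]:
        return {
            (u, v): d["raw_weight"] for u, v, d in self.graph.edges(data=True)
        }

    def sign_counts(self) -> tuple[int, int, int]:
        """(positive, negative, zero) raw-weight edge counts."""
        raw = np.array(
            [d["raw_weight"] for _, _, d in self.graph.edges(data=True)]
        )
        return int((raw > 0).sum()), int((raw < 0).sum()), int((raw == 0).sum())

    def unsigned_graph(self) -> nx.Graph:
        """Unweighted view used by topological metrics."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(self.graph.edges)
        return g

    def set_node_attribute(self, name: str, values: dict) -> None:
        nx.set_node_attributes(self.graph, values, name)


def build_network(
    corr: CorrelationResult,
    include_rule: str = "auto",
    alpha: float = 0.05,
    min_abs_corr: float = 0.0,
    taxonomy: list[str] | None = None,
) -> CooccurrenceNetwork:
    """Build the co-occurrence graph from a correlation result.

    ``include_rule`` is one of:

    - ``"pvalue"``: keep edge (i, j) iff p_ij < alpha (requires p-values);
    - ``"magnitude"``: keep iff |rho_ij| >= min_abs_corr;
    - ``"all"``: keep every pair (complete graph);
    - ``"auto"`` (default): ``pvalue`` when p-values are present, else
      ``magnitude`` — with the default ``min_abs_corr=0`` this keeps the
      full normalized matrix, the non-destructive default.
    """
    if include_rule == "auto":
        include_rule = "pvalue" if corr.pvalues is not None else "magnitude"
    if include_rule == "pvalue" and corr.pvalues is None:
        raise ValueError("include_rule='pvalue' requires p-values")
    if include_rule not in ("pvalue", "magnitude", "all"):
        raise ValueError(f"unknown include_rule {include_rule!r}")

    ids = corr.taxon_ids
    rho = corr.correlations
    g = nx.Graph()
    g.add_nodes_from(ids)
    if taxonomy is not None:
        nx.set_node_attributes(g, dict(zip(ids, taxonomy)), "taxonomy")
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if include_rule == "pvalue":
                keep = corr.pvalues[i, j] < alpha
            elif include_rule == "magnitude":
                keep = abs(rho[i, j]) >= min_abs_corr
            else:
                keep = True
            if keep:
                g.add_edge(ids[i], ids[j], raw_weight=float(rho[i, j]))
    return CooccurrenceNetwork(g)


def export_network(
    net: CooccurrenceNetwork, path: str | Path, format: str = "auto"
) -> None:
    """Write the network as GraphML or a 4-column edge list.

    GraphML preserves isolated nodes and node attributes; the edge list
    has columns (u, v, raw_weight, norm_weight).
    """
    path = Path(path)
    if format == "auto":
        format = "graphml" if path.suffix == ".graphml" else "edge_list"
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edge_list":
        rows = [
            (u, v, d["raw_weight"], d["norm_weight"])
            for u, v, d in net.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["u", "v", "raw_weight", "norm_weight"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def load_network(path: str | Path, format: str = "auto") -> CooccurrenceNetwork:
    """Re-import a network written by :func:`export_network`."""
    path = Path(path)
    if format == "auto":
        format = "graphml" if path.suffix == ".graphml" else "edge_list"
    if format == "graphml":
        g = nx.read_graphml(path)
        g = nx.Graph(g)
    elif format == "edge_list":
        df = pd.read_csv(path)
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(str(row["u"]), str(row["v"]), raw_weight=float(row["raw_weight"]))
    else:
        raise ValueError(f"unknown format {format!r}")
    return CooccurrenceNetwork(g)
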