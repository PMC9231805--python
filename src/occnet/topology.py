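"""Global topology metrics, null-model distributions and degree CCDFs.

The small-world index follows Humphries & Gurney:
``SW = (cc / cc_rand) / (l / l_rand)`` where cc and l are the clustering
coefficient and average shortest path length of the observed network and
the *_rand values come from Erdos-Renyi graphs matched on node count and
density; the mean SW over the matched replicates is returned. Values
above 1 indicate small-world character.

Path-based metrics (l, diameter) are computed on the giant component
when the graph is disconnected, and flagged as such. All topological
metrics use the unweighted edge set; only the positive:negative ratio
looks at raw edge signs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import CooccurrenceNetwork
from .synthetic import TOPOLOGIES, matched_graph

__all__ = [
    "TopologySummary",
    "NullDistribution",
    "DegreeDistribution",
    "summarize",
    "null_distributions",
    "degree_ccdf",
    "compare_ccdf",
]


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    avg_degree: float
    degree_sd: float
    pos_neg_ratio: float
    avg_shortest_path: float
    clustering_coefficient: float
    modularity: float
    diameter: float
    small_world_index: float
    giant_component_only: bool = False

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "avg_degree": self.avg_degree,
            "degree_sd": self.degree_sd,
            "pos_neg_ratio": self.pos_neg_ratio,
            "avg_shortest_path": self.avg_shortest_path,
            "clustering_coefficient": self.clustering_coefficient,
            "modularity": self.modularity,
            "diameter": self.diameter,
            "small_world_index": self.small_world_index,
            "giant_component_only": self.giant_component_only,
        }


@dataclass
class NullDistribution:
    """Per-replicate metric samples under one canonical topology."""

    topology_name: str
    samples: pd.DataFrame
    n_replicates: int
    n_nodes: int
    density: float
    avg_degree: float
    #: empirical quantile of each reference metric within this null
    reference_quantiles: dict[str, float] = field(default_factory=dict)


@dataclass
class DegreeDistribution:
    bin_edges: np.ndarray
    pdf: np.ndarray
    cdf: np.ndarray
    ccdf: np.ndarray


def _giant(g: nx.Graph) -> tuple[nx.Graph, bool]:
    if g.number_of_nodes() == 0 or nx.is_connected(g):
        return g, False
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    return giant, True


def _path_metrics(g: nx.Graph) -> tuple[float, float, bool]:
    """(avg shortest path, diameter, giant_component_only)."""
    if g.number_of_edges() == 0:
        return np.nan, np.nan, False
    sub, restricted = _giant(g)
    return (
        nx.average_shortest_path_length(sub),
        float(nx.diameter(sub)),
        restricted,
    )


def _modularity(g: nx.Graph) -> float:
    if g.number_of_edges() == 0:
        return np.nan
    parts = nx.community.greedy_modularity_communities(g)
    return nx.community.modularity(g, parts)


def small_world_index(
    g: nx.Graph, n_replicates: int = 50, rng: np.random.Generator | None = None
) -> float:
    """Mean Humphries-Gurney SW over matched Erdos-Renyi replicates."""
    rng = rng or np.random.default_rng()
    cc = nx.average_clustering(g)
    l, _, _ = _path_metrics(g)
    if not np.isfinite(l) or cc == 0:
        return np.nan
    n, p = g.number_of_nodes(), nx.density(g)
    values = []
    for _ in range(n_replicates):
        r = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        cc_rand = nx.average_clustering(r)
        l_rand, _, _ = _path_metrics(r)
        if cc_rand == 0 or not np.isfinite(l_rand) or l_rand == 0:
            continue
        values.append((cc / cc_rand) / (l / l_rand))
    return float(np.mean(values)) if values else np.nan


def summarize(
    net: CooccurrenceNetwork, sw_replicates: int = 50, seed: int | None = None
) -> TopologySummary:
    """Global metric summary of a signed network.

    Edgeless networks get NaN markers for path-based metrics and SW
    rather than exceptions; a network with no negative edges reports a
    pos_neg_ratio of +inf.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    g = net.unsigned_graph()
    degrees = np.array([d for _, d in g.degree()])
    pos, neg, _ = net.sign_counts()
    pos_neg = pos / neg if neg else (np.inf if pos else np.nan)
    l, diam, restricted = _path_metrics(g)
    rng = np.random.default_rng(seed)
    sw = (
        small_world_index(g, sw_replicates, rng)
        if g.number_of_edges() > 0
        else np.nan
    )
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        density=nx.density(g),
        avg_degree=float(degrees.mean()),
        degree_sd=float(degrees.std()),
        pos_neg_ratio=pos_neg,
        avg_shortest_path=l,
        clustering_coefficient=nx.average_clustering(g),
        modularity=_modularity(g),
        diameter=diam,
        small_world_index=sw,
        giant_component_only=restricted,
    )


def _replicate_metrics(
    g: nx.Graph, rng: np.random.Generator, sw_replicates: int
) -> dict:
    degrees = np.array([d for _, d in g.degree()])
    l, diam, _ = _path_metrics(g)
    return {
        "density": nx.density(g),
        "avg_degree": float(degrees.mean()),
        "degree_sd": float(degrees.std()),
        "avg_shortest_path": l,
        "clustering_coefficient": nx.average_clustering(g),
        "modularity": _modularity(g),
        "diameter": diam,
        "small_world_index": small_world_index(g, sw_replicates, rng),
    }


def null_distributions(
    reference: TopologySummary,
    topologies: tuple[str, ...] = TOPOLOGIES,
    n_replicates: int = 50,
    seed: int | None = None,
    sw_replicates: int = 10,
) -> list[NullDistribution]:
    """Metric distributions under matched canonical topologies.

    Each replicate graph is matched to the reference on node count,
    density and average degree (weights play no role in the unweighted
    metrics, so replicate weights are not drawn here). For every metric
    the reference value's empirical quantile within the null sample is
    reported: quantiles near 1 mean the observed network exceeds
    essentially all replicates of that topology.
    """
    if reference.n_nodes < 10:
        raise ValueError("need a reference network with >= 10 nodes")
    rng = np.random.default_rng(seed)
    out = []
    for topo in topologies:
        rows = []
        for _ in range(n_replicates):
            g = matched_graph(
                topo, reference.n_nodes, reference.density, rng,
                avg_degree=reference.avg_degree,
            )
            rows.append(_replicate_metrics(g, rng, sw_replicates))
        df = pd.DataFrame(rows)
        achieved = df["density"].mean()
        if abs(achieved - reference.density) > 0.1 * max(reference.density, 1e-12):
            warnings.warn(
                f"{topo}: achievable density {achieved:.4f} deviates from "
                f"reference {reference.density:.4f} by more than 10%",
                stacklevel=2,
            )
        ref = reference.to_dict()
        quantiles = {
            m: float((df[m].dropna() <= ref[m]).mean())
            for m in df.columns
            if np.isfinite(ref.get(m, np.nan))
        }
        out.append(
            NullDistribution(
                topology_name=topo,
                samples=df,
                n_replicates=n_replicates,
                n_nodes=reference.n_nodes,
                density=reference.density,
                avg_degree=reference.avg_degree,
                reference_quantiles=quantiles,
            )
        )
    return out


def degree_ccdf(
    net: CooccurrenceNetwork | nx.Graph, n_bins: int | str = "auto"
) -> DegreeDistribution:
    """Binned degree distribution with PDF, CDF and CCDF = 1 - CDF.

    ``n_bins="auto"`` uses unit-width integer bins (exact for integer
    degrees); an integer requests that many equal-width bins over the
    degree range.
    """
    g = net.unsigned_graph() if isinstance(net, CooccurrenceNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("need at least one node")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    if n_bins == "auto":
        edges = np.arange(degrees.min(), degrees.max() + 2) - 0.5
    else:
        edges = np.histogram_bin_edges(degrees, bins=int(n_bins))
    freq, edges = np.histogram(degrees, bins=edges)
    pdf = freq / freq.sum()
    cdf = np.cumsum(pdf)
    return DegreeDistribution(bin_edges=edges, pdf=pdf, cdf=cdf, ccdf=1.0 - cdf)


def compare_ccdf(
    net: CooccurrenceNetwork, seed: int | None = None
) -> pd.DataFrame:
    """Observed CCDF next to one matched replicate per canonical topology.

    Returns a long-form table (curve, degree, ccdf) on shared unit bins,
    ready for a log-log plot.
    """
    if net.n_edges == 0:
        raise ValueError("need a non-trivial network")
    g = net.unsigned_graph()
    rng = np.random.default_rng(seed)
    graphs = {"observed": g}
    density = nx.density(g)
    avg_degree = 2 * g.number_of_edges() / g.number_of_nodes()
    for topo in TOPOLOGIES:
        graphs[topo] = matched_graph(
            topo, g.number_of_nodes(), density, rng, avg_degree=avg_degree
        )
    max_deg = max(max(d for _, d in gr.degree()) for gr in graphs.values())
    edges = np.arange(0, max_deg + 2) - 0.5
    rows = []
    for name, gr in graphs.items():
        degrees = [d for _, d in gr.degree()]
        freq, _ = np.histogram(degrees, bins=edges)
        pdf = freq / freq.sum()
        ccdf = 1.0 - np.cumsum(pdf)
        for k, c in enumerate(ccdf):
            rows.append({"curve": name, "degree": k, "ccdf": c})
    return pd.DataFrame(rows)
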