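"""Percolation: node-removal robustness simulation.

Nodes are removed cumulatively — a fixed fraction of the original node
count per step (or one whole group per step) — and after every step the
surviving network's degradation metrics are recorded: density, average
degree, number of connected components, giant-component size and
fraction, Louvain community count and modularity. Removal strategies:
uniformly random, by centrality (degree / closeness / betweenness,
highest first, ranked on the intact network), or by a user-supplied
grouping such as taxonomy or cluster labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .communities import louvain_partition_graph
from .network import CooccurrenceNetwork

__all__ = ["PercolationTrace", "percolate", "robustness_report"]

STRATEGIES = ("random", "degree", "closeness", "betweenness", "group")
TRACKED_METRICS = (
    "n_nodes",
    "n_edges",
    "density",
    "avg_degree",
    "n_components",
    "giant_size",
    "giant_fraction",
    "n_louvain_communities",
    "modularity",
)


@dataclass
class PercolationTrace:
    strategy: str
    records: pd.DataFrame  # one row per step, step 0 = intact network
    seed: int | None = None
    group_order: list | None = None

    @property
    def n_steps(self) -> int:
        return len(self.records)


def _step_metrics(g: nx.Graph, n_original: int, seed: int) -> dict:
    n = g.number_of_nodes()
    if n == 0:
        return {
            "n_nodes": 0, "n_edges": 0, "density": 0.0, "avg_degree": 0.0,
            "n_components": 0, "giant_size": 0, "giant_fraction": 0.0,
            "n_louvain_communities": 0, "modularity": np.nan,
        }
    components = list(nx.connected_components(g))
    giant = max(len(c) for c in components)
    if g.number_of_edges() > 0:
        partition = louvain_partition_graph(g, seed=seed)
        n_comm = len(set(partition.values()))
        groups = {}
        for node, label in partition.items():
            groups.setdefault(label, set()).add(node)
        modularity = nx.community.modularity(g, groups.values())
    else:
        n_comm = n
        modularity = np.nan
    return {
        "n_nodes": n,
        "n_edges": g.number_of_edges(),
        "density": nx.density(g) if n > 1 else 0.0,
        "avg_degree": 2 * g.number_of_edges() / n,
        "n_components": len(components),
        "giant_size": giant,
        "giant_fraction": giant / n,
        "n_louvain_communities": n_comm,
        "modularity": modularity,
    }


def _removal_order(
    g: nx.Graph,
    strategy: str,
    rng: np.random.Generator,
    groups: dict | None,
) -> list:
    nodes = list(g.nodes)
    if strategy == "random":
        return [nodes[i] for i in rng.permutation(len(nodes))]
    centrality_fn = {
        "degree": nx.degree_centrality,
        "closeness": nx.closeness_centrality,
        "betweenness": nx.betweenness_centrality,
    }.get(strategy)
    if centrality_fn is None:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    scores = centrality_fn(g)
    # highest centrality first; ties broken by node id for determinism
    return sorted(nodes, key=lambda v: (-scores[v], str(v)))


def percolate(
    net: CooccurrenceNetwork,
    strategy: str = "random",
    step_fraction: float = 0.1,
    groups: dict | None = None,
    group_order: list | None = None,
    seed: int | None = None,
    adaptive: bool = False,
) -> PercolationTrace:
    """Simulate cumulative node removal until the network is empty.

    ``step_fraction`` of the *original* node count is removed per step
    (ceil, so the simulation always terminates). ``strategy="group"``
    removes one whole group per step, in ``group_order`` or by
    descending group size. ``adaptive=True`` re-ranks centralities on
    the surviving network before every step instead of once.
    """
    if strategy != "group" and not 0 < step_fraction <= 1:
        raise ValueError("step_fraction must be in (0, 1]")
    g = net.unsigned_graph()
    n0 = g.number_of_nodes()
    rng = np.random.default_rng(seed)
    step_seeds = np.random.SeedSequence(seed if seed is not None else 0).spawn(
        n0 + 2
    )

    order_used: list | None = None
    if strategy == "group":
        if groups is None:
            raise ValueError("strategy='group' requires a node->label mapping")
        missing = set(g.nodes) - set(groups)
        if missing:
            raise ValueError(f"groups missing nodes: {sorted(missing)[:5]}")
        members: dict = {}
        for node in g.nodes:
            members.setdefault(groups[node], []).append(node)
        if group_order is None:
            order_used = sorted(
                members, key=lambda lab: (-len(members[lab]), str(lab))
            )
        else:
            order_used = list(group_order)
        batches = [members[lab] for lab in order_used]
    elif adaptive:
        batches = None  # recomputed per step
    else:
        removal = _removal_order(g, strategy, rng, groups)
        per_step = math.ceil(step_fraction * n0)
        batches = [
            removal[i : i + per_step] for i in range(0, len(removal), per_step)
        ]

    def seed_for(step: int) -> int:
        return int(step_seeds[step].generate_state(1)[0] % (2**31))

    rows = [dict(fraction_removed=0.0, n_removed=0, **_step_metrics(g, n0, seed_for(0)))]
    removed_total = 0
    step = 0
    if adaptive and strategy != "group":
        per_step = math.ceil(step_fraction * n0)
        while g.number_of_nodes() > 0:
            step += 1
            batch = _removal_order(g, strategy, rng, groups)[:per_step]
            g.remove_nodes_from(batch)
            removed_total += len(batch)
            rows.append(
                dict(
                    fraction_removed=removed_total / n0,
                    n_removed=len(batch),
                    **_step_metrics(g, n0, seed_for(step)),
                )
            )
    else:
        for batch in batches:
            step += 1
            g.remove_nodes_from(batch)
            removed_total += len(batch)
            rows.append(
                dict(
                    fraction_removed=removed_total / n0,
                    n_removed=len(batch),
                    **_step_metrics(g, n0, seed_for(step)),
                )
            )
    return PercolationTrace(
        strategy=strategy,
        records=pd.DataFrame(rows),
        seed=seed,
        group_order=order_used,
    )


def robustness_report(trace: PercolationTrace) -> pd.DataFrame:
    """Area under each metric trajectory, plus the half-giant threshold.

    The area is the trapezoidal integral of the metric against the
    removed fraction — larger giant-fraction area means slower
    degradation. The row ``giant_half_fraction`` holds the removal
    fraction at which the giant fraction first drops below 0.5 (NaN if
    it never does).
    """
    rec = trace.records
    if rec.empty:
        raise ValueError("empty trace")
    x = rec["fraction_removed"].to_numpy()
    rows = []
    for metric in TRACKED_METRICS:
        y = rec[metric].to_numpy(dtype=float)
        ok = np.isfinite(y)
        area = float(np.trapezoid(y[ok], x[ok])) if ok.sum() >= 2 else np.nan
        rows.append({"metric": metric, "area_under_trajectory": area})
    below = rec.loc[rec["giant_fraction"] < 0.5, "fraction_removed"]
    rows.append(
        {
            "metric": "giant_half_fraction",
            "area_under_trajectory": float(below.iloc[0]) if len(below) else np.nan,
        }
    )
    return pd.DataFrame(rows)
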