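"""Structural balance: signed triangle census.

A triangle is balanced iff the product of its three edge signs is
positive — "my friend's friend is my friend" and "my friend's enemy is
my enemy". The four types, by the multiset of signs, are ppp and pmm
(balanced) versus ppm and mmm (imbalanced).

The default census enumerates *every* triangle (3-clique) of the graph.
A ``cycle_basis`` mode is also provided that restricts the census to the
length-3 cycles of a cycle basis; a cycle basis does not contain every
triangle, so this mode systematically undercounts and exists only for
comparison with pipelines that used it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import CooccurrenceNetwork

__all__ = ["TriadCensus", "classify_triad", "triad_census"]

TRIAD_TYPES = ("ppp", "pmm", "ppm", "mmm")
BALANCED_TYPES = ("ppp", "pmm")


@dataclass
class TriadCensus:
    counts: dict[str, int]
    total_triangles: int
    balanced_fraction: float  # NaN when no triangles exist

    @property
    def percentages(self) -> dict[str, float]:
        if self.total_triangles == 0:
            return {t: np.nan for t in TRIAD_TYPES}
        return {
            t: 100.0 * self.counts[t] / self.total_triangles for t in TRIAD_TYPES
        }

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total_triangles": self.total_triangles,
            "balanced_fraction": self.balanced_fraction,
            "percentages": self.percentages,
        }


def classify_triad(sign_a: float, sign_b: float, sign_c: float) -> tuple[str, str]:
    """Classify a signed triangle; returns (verdict, type code).

    Signs are given as +/-1 (any nonzero number works; only the sign is
    used). Symmetric in the three edges.
    """
    signs = [sign_a, sign_b, sign_c]
    if any(s == 0 for s in signs):
        raise ValueError("zero-weight edges are not edges; drop them upstream")
    n_neg = sum(s < 0 for s in signs)
    code = {0: "ppp", 1: "ppm", 2: "pmm", 3: "mmm"}[n_neg]
    verdict = "balanced" if code in BALANCED_TYPES else "imbalanced"
    return verdict, code


def _signed_graph(net: CooccurrenceNetwork) -> nx.Graph:
    """Copy without exact-zero-weight edges (a zero correlation is no edge)."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        if d["raw_weight"] != 0:
            g.add_edge(u, v, raw_weight=d["raw_weight"])
    return g


def _iter_triangles(g: nx.Graph):
    """Every 3-clique exactly once, via ordered neighbor intersection."""
    order = {node: k for k, node in enumerate(g.nodes)}
    for u, v in g.edges:
        if order[u] > order[v]:
            u, v = v, u
        common = set(g[u]) & set(g[v])
        for w in common:
            if order[w] > order[v]:
                yield u, v, w


def triad_census(
    net: CooccurrenceNetwork, mode: str = "all_triangles"
) -> TriadCensus:
    """Count signed triangles by type.

    ``mode="all_triangles"`` (default) enumerates every 3-clique;
    ``mode="cycle_basis"`` keeps only length-3 cycles of a cycle basis
    (undercounts; comparison mode only). With no triangles the census
    reports total 0 and a NaN balanced fraction.
    """
    g = _signed_graph(net)
    if mode == "all_triangles":
        triangles = _iter_triangles(g)
    elif mode == "cycle_basis":
        triangles = (tuple(c) for c in nx.cycle_basis(g) if len(c) == 3)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    counts = {t: 0 for t in TRIAD_TYPES}
    for u, v, w in triangles:
        _, code = classify_triad(
            g[u][v]["raw_weight"], g[v][w]["raw_weight"], g[u][w]["raw_weight"]
        )
        counts[code] += 1
    total = sum(counts.values())
    balanced = (
        (counts["ppp"] + counts["pmm"]) / total if total else float("nan")
    )
    return TriadCensus(counts=counts, total_triangles=total, balanced_fraction=balanced)
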