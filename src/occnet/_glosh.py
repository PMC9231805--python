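"""GLOSH (Global-Local Outlier Score from Hierarchies).

Scores each point by how early it falls out of the density hierarchy
that HDBSCAN builds: single linkage on mutual-reachability distances,
condensed with a minimum cluster size. A point p that leaves cluster c
at density level lambda_p = 1/d receives

    score(p) = (lambda_max(c) - lambda_p) / lambda_max(c)

where lambda_max(c) is the highest density attained anywhere in c's
subtree. Scores lie in [0, 1]; points surviving into the densest core
score near 0, isolated points score near 1.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = ["glosh_scores"]

_EPS = 1e-12


def _core_distances(dist: np.ndarray, min_samples: int) -> np.ndarray:
    n = dist.shape[0]
    k = min(max(min_samples - 1, 1), n - 1)  # self sits at index 0
    return np.partition(dist, k, axis=1)[:, k]


def glosh_scores(
    dist: np.ndarray, min_samples: int = 5, min_cluster_size: int = 15
) -> np.ndarray:
    """GLOSH outlier scores from a symmetric distance matrix."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("dist must be a square distance matrix")
    if n < 3:
        return np.zeros(n)

    core = _core_distances(dist, min_samples)
    mreach = np.maximum(np.maximum.outer(core, core), dist)
    np.fill_diagonal(mreach, 0.0)
    merge = linkage(squareform(mreach, checks=False), method="single")

    # children and merge heights of the single-linkage tree;
    # node ids: 0..n-1 points, n..2n-2 internal
    children = {n + t: (int(merge[t, 0]), int(merge[t, 1])) for t in range(n - 1)}
    height = {n + t: merge[t, 2] for t in range(n - 1)}
    sizes = np.ones(2 * n - 1, dtype=int)
    for t in range(n - 1):
        a, b = children[n + t]
        sizes[n + t] = sizes[a] + sizes[b]

    def leaves(node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend(children[v])
        return out

    # condense: walk down, splitting into new clusters only when both
    # sides reach min_cluster_size; otherwise points fall out at 1/d
    point_lambda = np.zeros(n)
    point_cluster = np.zeros(n, dtype=int)
    cluster_parent: dict[int, int] = {}
    next_cluster = 0
    root = 2 * n - 2
    stack = [(root, next_cluster)]
    next_cluster += 1
    while stack:
        node, cluster = stack.pop()
        if node < n:
            point_lambda[node] = np.inf  # singleton carried as its own cluster
            point_cluster[node] = cluster
            continue
        lam = 1.0 / max(height[node], _EPS)
        left, right = children[node]
        big_left = sizes[left] >= min_cluster_size
        big_right = sizes[right] >= min_cluster_size
        if big_left and big_right:
            for child in (left, right):
                cluster_parent[next_cluster] = cluster
                stack.append((child, next_cluster))
                next_cluster += 1
        elif big_left or big_right:
            keep, spill = (left, right) if big_left else (right, left)
            for p in leaves(spill):
                point_lambda[p] = lam
                point_cluster[p] = cluster
            stack.append((keep, cluster))
        else:
            for p in leaves(node):
                point_lambda[p] = lam
                point_cluster[p] = cluster

    finite = point_lambda[np.isfinite(point_lambda)]
    cap = finite.max() if finite.size else 1.0
    lam_capped = np.minimum(point_lambda, cap)

    deaths = np.zeros(next_cluster)
    for c in range(next_cluster):
        mask = point_cluster == c
        if mask.any():
            deaths[c] = lam_capped[mask].max()
    for c in range(next_cluster - 1, 0, -1):  # children have higher ids
        parent = cluster_parent[c]
        deaths[parent] = max(deaths[parent], deaths[c])

    death = deaths[point_cluster]
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (death - lam_capped) / death
    scores[~np.isfinite(scores)] = 0.0
    return np.clip(scores, 0.0, 1.0)
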