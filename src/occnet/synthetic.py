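"""Synthetic benchmark data with known ground truth.

Two families of generators:

- multinomial log-normal communities with a planted basis correlation
  matrix (the standard validation design for compositional correlation
  estimators): latent log abundances are multivariate normal, fractions
  follow by exponentiation and closure, and counts are multinomial at a
  fixed sequencing depth;
- signed networks with a planted canonical topology (Erdos-Renyi random,
  Watts-Strogatz small-world, Barabasi-Albert scale-free) and edge
  weights uniform in [-1, 1], for exercising the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .abundance import AbundanceTable
from .network import CooccurrenceNetwork

__all__ = [
    "CommunitySpec",
    "generate_community",
    "generate_sparse_basis",
    "generate_signed_network",
    "matched_graph",
    "nearest_psd_correlation",
]

TOPOLOGIES = ("random", "small_world", "scale_free")


def nearest_psd_correlation(matrix: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD one with unit diagonal.

    Eigenvalue clipping at ``eps`` followed by rescaling the diagonal
    back to 1; entries stay in [-1, 1].
    """
    m = (np.asarray(matrix, float) + np.asarray(matrix, float).T) / 2.0
    vals, vecs = np.linalg.eigh(m)
    m = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class CommunitySpec:
    """Parameters of a multinomial log-normal community.

    ``basis_correlation`` is the planted correlation of the latent log
    abundances (identity by default); ``log_mean``/``log_sd`` are the
    latent normal's per-taxon mean and standard deviation (defaults 0
    and 1); ``depth`` is the multinomial read count per sample.
    """

    n_taxa: int
    n_samples: int
    depth: int = 10_000
    basis_correlation: np.ndarray | None = None
    log_mean: np.ndarray | None = None
    log_sd: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.basis_correlation is None:
            self.basis_correlation = np.eye(self.n_taxa)
        self.basis_correlation = np.asarray(self.basis_correlation, float)
        if self.basis_correlation.shape != (self.n_taxa, self.n_taxa):
            raise ValueError("basis_correlation dimension must equal n_taxa")
        if not np.allclose(self.basis_correlation, self.basis_correlation.T):
            raise ValueError("basis_correlation must be symmetric")
        min_eig = float(np.linalg.eigvalsh(self.basis_correlation).min())
        if min_eig < -1e-8:
            raise ValueError(
                f"basis_correlation is not positive semi-definite (min "
                f"eigenvalue {min_eig:.3g}); repair it with "
                "nearest_psd_correlation()"
            )
        self.log_mean = (
            np.zeros(self.n_taxa)
            if self.log_mean is None
            else np.asarray(self.log_mean, float)
        )
        self.log_sd = (
            np.ones(self.n_taxa)
            if self.log_sd is None
            else np.asarray(self.log_sd, float)
        )
        if self.log_mean.shape != (self.n_taxa,) or self.log_sd.shape != (self.n_taxa,):
            raise ValueError("log_mean and log_sd must have length n_taxa")
        if np.any(self.log_sd <= 0):
            raise ValueError("log_sd must be positive")


def generate_community(spec: CommunitySpec) -> tuple[AbundanceTable, np.ndarray]:
    """Draw a community and return (table, planted basis correlation).

    Per sample: latent log abundances ~ N(log_mean, S rho S) with
    S = diag(log_sd); fractions are the closed exponentials; counts are
    multinomial(depth, fractions). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cov = spec.basis_correlation * np.outer(spec.log_sd, spec.log_sd)
    z = rng.multivariate_normal(
        spec.log_mean, cov, size=spec.n_samples, method="svd"
    )
    x = np.exp(z)
    fractions = x / x.sum(axis=1, keepdims=True)
    counts = np.empty((spec.n_samples, spec.n_taxa))
    for s in range(spec.n_samples):
        counts[s] = rng.multinomial(spec.depth, fractions[s])
    width = len(str(spec.n_taxa))
    table = AbundanceTable(
        taxon_ids=[f"taxon_{i + 1:0{width}d}" for i in range(spec.n_taxa)],
        sample_ids=[f"sample_{s + 1:03d}" for s in range(spec.n_samples)],
        counts=counts.T,
    )
    return table, spec.basis_correlation.copy()


def generate_sparse_basis(
    n_taxa: int,
    n_strong: int,
    strength: float = 0.8,
    seed: int = 0,
    p_negative: float = 0.5,
) -> np.ndarray:
    """Identity plus ``n_strong`` planted off-diagonal pairs at +/- strength.

    When the pairs fit node-disjointly (2 * n_strong <= n_taxa) they are
    sampled without sharing taxa, which keeps the matrix exactly PSD and
    the planted values exact; otherwise arbitrary pairs are planted and
    the matrix projected to the nearest PSD correlation.
    """
    if not 0 < strength < 1:
        raise ValueError("strength must be in (0, 1)")
    max_pairs = n_taxa * (n_taxa - 1) // 2
    if n_strong > max_pairs:
        raise ValueError(f"n_strong={n_strong} exceeds {max_pairs} possible pairs")
    rng = np.random.default_rng(seed)
    basis = np.eye(n_taxa)
    if n_strong == 0:
        return basis
    if 2 * n_strong <= n_taxa:
        nodes = rng.permutation(n_taxa)[: 2 * n_strong]
        pairs = [(nodes[2 * k], nodes[2 * k + 1]) for k in range(n_strong)]
    else:
        all_pairs = [(i, j) for i in range(n_taxa) for j in range(i + 1, n_taxa)]
        idx = rng.choice(len(all_pairs), size=n_strong, replace=False)
        pairs = [all_pairs[k] for k in idx]
    for i, j in pairs:
        sign = -1.0 if rng.random() < p_negative else 1.0
        basis[i, j] = basis[j, i] = sign * strength
    if 2 * n_strong > n_taxa:
        basis = nearest_psd_correlation(basis)
    return basis


def matched_graph(
    topology: str,
    n_nodes: int,
    density: float,
    rng: np.random.Generator,
    avg_degree: float | None = None,
    rewiring_p: float = 0.1,
) -> nx.Graph:
    """Unweighted graph of a canonical topology matched on nodes/density.

    random: G(n, p=density); small_world: Watts-Strogatz ring with
    k = round(avg_degree) forced even and rewiring probability 0.1;
    scale_free: Barabasi-Albert with attachment m = round(avg_degree/2).
    """
    if avg_degree is None:
        avg_degree = density * (n_nodes - 1)
    seed = int(rng.integers(2**31))
    if topology == "random":
        return nx.gnp_random_graph(n_nodes, density, seed=seed)
    if topology == "small_world":
        k = int(round(avg_degree))
        k -= k % 2
        k = max(2, min(k, n_nodes - 1 - (n_nodes - 1) % 2))
        return nx.watts_strogatz_graph(n_nodes, k, rewiring_p, seed=seed)
    if topology == "scale_free":
        m = max(1, int(round(avg_degree / 2)))
        m = min(m, n_nodes - 1)
        return nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    raise ValueError(f"unknown topology {topology!r}; choose from {TOPOLOGIES}")


def generate_signed_network(
    n_nodes: int,
    topology: str = "random",
    density: float = 0.1,
    p_negative: float = 0.5,
    seed: int = 0,
) -> CooccurrenceNetwork:
    """Signed network with a planted topology and uniform [-1, 1] weights.

    Weight magnitudes are uniform in (0, 1]; the negative-sign fraction
    is controlled by ``p_negative`` (0 gives an all-positive network).
    """
    if not 0 <= p_negative <= 1:
        raise ValueError("p_negative must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = matched_graph(topology, n_nodes, density, rng)
    out = nx.Graph()
    out.add_nodes_from(f"node_{i:04d}" for i in range(n_nodes))
    for u, v in g.edges:
        mag = 1.0 - rng.random()  # uniform in (0, 1]: zero weights are non-edges
        sign = -1.0 if rng.random() < p_negative else 1.0
        out.add_edge(f"node_{u:04d}", f"node_{v:04d}", raw_weight=sign * mag)
    return CooccurrenceNetwork(out)
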