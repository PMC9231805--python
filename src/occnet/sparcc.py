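"""SparCC: basis correlations from compositional abundance data.

Relative-abundance (compositional) data induce spurious negative
correlations because fractions are constrained to sum to one. SparCC
sidesteps the constraint by working with log-ratio variances

    t_ij = Var_s[ log(x_is / x_js) ] = omega_i + omega_j - 2 rho_ij sqrt(omega_i omega_j)

where omega_i is the variance of taxon i's latent log absolute abundance
and rho_ij the latent ("basis") correlation. Assuming the correlation
network is sparse, the sum of correlation terms is neglected, leaving a
linear system for the basis variances omega; rho then follows in closed
form. Pairs that nonetheless come out strongly correlated are excluded
from the system one at a time and the system re-solved ("exclusion
iterations"). Sampling zeros are handled by drawing fractions from a
per-sample Dirichlet(counts + 1) posterior, repeated over outer
iterations whose estimates are aggregated entrywise by the median.

Intermediate per-iteration estimates can be spilled to an HDF5 scratch
file (one dataset per iteration, ``/iter_<k>/rho``) so that the
aggregation stage streams over row blocks instead of holding all
iterations in RAM — the path that keeps very large taxon sets feasible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, write_matrix

__all__ = [
    "SparccConfig",
    "CorrelationResult",
    "variation_matrix",
    "basis_correlations",
    "run_sparcc",
    "pvalues",
]

_MEDIAN_BLOCK_ROWS = 512


@dataclass(frozen=True)
class SparccConfig:
    """SparCC estimation settings.

    Defaults follow the parameter sweep behind the reference pipeline:
    50 outer resampling iterations, at most 10 excluded pairs per
    estimate with exclusion threshold 0.10, and 100 permutations for
    p-values (50 is the quick-mode default, see ``quick()``).
    """

    n_iterations: int = 50
    exclusion_threshold: float = 0.10
    exclusion_max: int = 10
    n_permutations: int = 100
    one_sided: bool = True
    seed: int = 0
    scratch_path: str | Path | None = None
    #: draw fractions from Dirichlet(counts + 1); disable only for
    #: zero-free data already expressed as fractions (diagnostic mode).
    resample_fractions: bool = True
    #: outer iterations used inside each p-value permutation (reduced
    #: relative to n_iterations purely for speed).
    permutation_iterations: int = 5

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.exclusion_threshold < 1:
            raise ValueError("exclusion_threshold must be in (0, 1)")
        if self.exclusion_max < 0:
            raise ValueError("exclusion_max must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def quick(cls, **kwargs) -> "SparccConfig":
        """Quick-run settings: 50 permutations instead of 100."""
        kwargs.setdefault("n_permutations", 50)
        return cls(**kwargs)


@dataclass
class CorrelationResult:
    """Symmetric basis-correlation matrix with optional one-sided p-values."""

    taxon_ids: list[str]
    correlations: np.ndarray
    pvalues: np.ndarray | None = None
    config: SparccConfig | None = None
    degenerate_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.correlations, dtype=float)
        n = len(self.taxon_ids)
        if c.shape != (n, n):
            raise ValueError(f"correlations shape {c.shape} != ({n}, {n})")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        self.correlations = c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.correlations, index=self.taxon_ids, columns=self.taxon_ids
        )

    def pvalues_frame(self) -> pd.DataFrame | None:
        if self.pvalues is None:
            return None
        return pd.DataFrame(self.pvalues, index=self.taxon_ids, columns=self.taxon_ids)

    def write(self, corr_path: str | Path, pval_path: str | Path | None = None) -> None:
        write_matrix(self.to_frame(), corr_path)
        if pval_path is not None:
            if self.pvalues is None:
                raise ValueError("no p-values to write")
            write_matrix(self.pvalues_frame(), pval_path)


def variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """Log-ratio variance matrix t_ij over samples.

    ``fractions`` is samples x taxa, strictly positive. t_ij is the
    sample variance (n-1 denominator) of log(x_i / x_j); computed via the
    covariance of log fractions: t_ij = v_i + v_j - 2 cov_ij.
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 2:
        raise ValueError("fractions must be samples x taxa")
    if np.any(f <= 0):
        raise ValueError(
            "fractions must be strictly positive; resample zeros upstream "
            "(Dirichlet(counts + 1))"
        )
    logf = np.log(f)
    cov = np.cov(logf, rowvar=False, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    t[t < 0] = 0.0  # numerical noise on proportional pairs
    return (t + t.T) / 2.0


def basis_correlations(
    t: np.ndarray,
    excluded_pairs: set[tuple[int, int]] | frozenset = frozenset(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the sparse-approximation system for basis variances and correlations.

    Under sparsity, summing t_ij over j gives a linear system
    ``M omega = rowsum(t)`` with M = 1 + (D-2) I. Excluded pairs drop out
    of both the row sums and M. Returns ``(omega, rho, degenerate)`` where
    ``degenerate`` flags taxa whose solved basis variance was <= 0; their
    correlations are set to 0 (diagonal stays 1) and rho is clamped to
    [-1, 1] elsewhere. Excluded pairs still receive a rho from the final
    omega and their t value.
    """
    t = np.asarray(t, dtype=float)
    d = t.shape[0]
    if t.shape != (d, d):
        raise ValueError("t must be square")
    if d < 3:
        raise ValueError("need at least 3 taxa for identifiability")
    m = np.ones((d, d)) + np.eye(d) * (d - 2)
    rowsum = t.sum(axis=1)
    for i, j in excluded_pairs:
        i, j = min(i, j), max(i, j)
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        rowsum[i] -= t[i, j]
        rowsum[j] -= t[i, j]
    omega = np.linalg.solve(m, rowsum)

    degenerate = omega <= 0
    safe = np.where(degenerate, np.nan, omega)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = 2.0 * np.sqrt(np.outer(safe, safe))
        rho = (safe[:, None] + safe[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    return omega, rho, degenerate


def _strongest_pair(
    rho: np.ndarray, excluded: set[tuple[int, int]]
) -> tuple[int, int, float]:
    """Most strongly correlated non-excluded off-diagonal pair.

    Ties break on the lexicographically lowest (row, col) pair.
    """
    a = np.abs(np.triu(rho, k=1))
    for i, j in excluded:
        a[min(i, j), max(i, j)] = -np.inf
    flat = np.argmax(a)  # argmax returns the first (lowest flat index) max
    i, j = np.unravel_index(flat, a.shape)
    return int(i), int(j), float(a[i, j])


def _estimate_once(fractions: np.ndarray, config: SparccConfig) -> np.ndarray:
    """One SparCC estimate (single fraction draw) with exclusion iterations."""
    t = variation_matrix(fractions)
    excluded: set[tuple[int, int]] = set()
    _, rho, _ = basis_correlations(t, excluded)
    while len(excluded) < config.exclusion_max:
        i, j, strength = _strongest_pair(rho, excluded)
        if strength <= config.exclusion_threshold:
            break
        excluded.add((i, j))
        _, rho, _ = basis_correlations(t, excluded)
    return rho


def _draw_fractions(
    counts: np.ndarray, rng: np.random.Generator, resample: bool
) -> np.ndarray:
    """Per-sample fractions from counts (taxa x samples) -> samples x taxa."""
    c = counts.T
    if not resample:
        totals = c.sum(axis=1, keepdims=True)
        if np.any(c <= 0):
            raise ValueError(
                "resample_fractions=False requires strictly positive counts"
            )
        return c / totals
    out = np.empty_like(c, dtype=float)
    for s in range(c.shape[0]):
        out[s] = rng.dirichlet(c[s] + 1.0)
    return out


def _blockwise_median(h5file, n_taxa: int, n_iter: int) -> np.ndarray:
    """Entrywise median over /iter_<k>/rho datasets, streamed by row block."""
    med = np.empty((n_taxa, n_taxa))
    for start in range(0, n_taxa, _MEDIAN_BLOCK_ROWS):
        stop = min(start + _MEDIAN_BLOCK_ROWS, n_taxa)
        stack = np.empty((n_iter, stop - start, n_taxa))
        for k in range(n_iter):
            h5file[f"iter_{k:04d}/rho"].read_direct(
                stack, np.s_[start:stop, :], np.s_[k]
            )
        med[start:stop] = np.median(stack, axis=0)
    return med


def run_sparcc(table: AbundanceTable, config: SparccConfig | None = None) -> CorrelationResult:
    """Estimate basis correlations for an abundance table.

    Per outer iteration, fractions are drawn from Dirichlet(counts + 1)
    per sample, the variation matrix computed, and the sparse system
    solved with exclusion iterations; estimates are aggregated entrywise
    by the median. Deterministic given ``config.seed``.
    """
    config = config or SparccConfig()
    if table.n_taxa < 3:
        raise ValueError("SparCC needs at least 3 taxa")
    if table.n_samples < 4:
        warnings.warn(
            f"only {table.n_samples} samples; correlation estimates will be "
            "very noisy",
            stacklevel=2,
        )
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_iterations)

    h5file = None
    estimates: list[np.ndarray] = []
    try:
        if config.scratch_path is not None:
            import h5py

            h5file = h5py.File(config.scratch_path, "w")
        for k in range(config.n_iterations):
            rng = np.random.default_rng(seeds[k])
            fractions = _draw_fractions(table.counts, rng, config.resample_fractions)
            rho = _estimate_once(fractions, config)
            if h5file is not None:
                h5file.create_dataset(f"iter_{k:04d}/rho", data=rho)
            else:
                estimates.append(rho)
        if h5file is not None:
            h5file.flush()
            corr = _blockwise_median(h5file, table.n_taxa, config.n_iterations)
        else:
            corr = np.median(np.stack(estimates), axis=0)
    finally:
        if h5file is not None:
            h5file.close()

    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationResult(
        taxon_ids=list(table.taxon_ids), correlations=corr, config=config
    )


def pvalues(
    table: AbundanceTable,
    observed: CorrelationResult,
    config: SparccConfig | None = None,
) -> np.ndarray:
    """Monte-Carlo permutation p-values for an observed correlation matrix.

    Each permutation independently shuffles every taxon's counts across
    samples (destroying all between-taxon association while preserving
    marginals) and re-runs SparCC with ``permutation_iterations`` outer
    iterations. One-sided p-values use the upper tail for rho >= 0 and
    the lower tail for rho < 0; two-sided uses |rho|. The add-one
    estimator bounds p in [1/(n+1), 1].
    """
    config = config or observed.config or SparccConfig()
    if list(observed.taxon_ids) != list(table.taxon_ids):
        raise ValueError("observed result does not match the table's taxa")
    obs = observed.correlations
    n = config.n_permutations
    perm_config = replace(
        config, n_iterations=config.permutation_iterations, scratch_path=None
    )
    root = np.random.SeedSequence((config.seed, 0x9E3779B9))
    seeds = root.spawn(n)

    exceed = np.zeros_like(obs)
    for p in range(n):
        rng = np.random.default_rng(seeds[p])
        shuffled = np.empty_like(table.counts)
        for i in range(table.n_taxa):
            shuffled[i] = rng.permutation(table.counts[i])
        perm_table = AbundanceTable(
            taxon_ids=list(table.taxon_ids),
            sample_ids=list(table.sample_ids),
            counts=shuffled,
            taxonomy=table.taxonomy,
        )
        perm_seed = int(seeds[p].generate_state(1)[0] % (2**31))
        perm = run_sparcc(perm_table, replace(perm_config, seed=perm_seed))
        r = perm.correlations
        if config.one_sided:
            exceed += np.where(obs >= 0, r >= obs, r <= obs)
        else:
            exceed += np.abs(r) >= np.abs(obs)

    pmat = (1.0 + exceed) / (n + 1.0)
    pmat = (pmat + pmat.T) / 2.0
    np.fill_diagonal(pmat, 0.0)
    return pmat
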