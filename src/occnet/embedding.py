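"""UMAP embedding and HDBSCAN clustering of taxa abundance profiles.

Each taxon is a point whose features are its per-sample relative
abundances; UMAP projects the taxa into two dimensions (Bray-Curtis
input metric, Hellinger output metric by default) and HDBSCAN clusters
the embedded points by density. Points assigned to no cluster are noise
(label -1); points whose GLOSH outlier score exceeds the configured
quantile of all scores are flagged as outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.metrics import pairwise_distances

from ._glosh import glosh_scores
from .abundance import AbundanceTable

__all__ = ["EmbeddingConfig", "EmbeddingResult", "embed_and_cluster", "export_clusters"]

_METRIC_ALIASES = {
    "bray-curtis": "braycurtis",
    "braycurtis": "braycurtis",
    "euclidean": "euclidean",
    "hellinger": "hellinger",
    "manhattan": "manhattan",
    "cosine": "cosine",
}


def _metric(name: str) -> str:
    try:
        return _METRIC_ALIASES[name.lower()]
    except KeyError:
        raise ValueError(f"unsupported metric {name!r}") from None


@dataclass(frozen=True)
class EmbeddingConfig:
    """UMAP + HDBSCAN settings (defaults follow the reference pipeline)."""

    n_neighbors: int = 15
    min_dist: float = 0.1
    n_components: int = 2
    input_metric: str = "bray-curtis"
    output_metric: str = "hellinger"
    hdb_min_cluster_size: int = 15
    hdb_min_samples: int = 5
    hdb_metric: str = "bray-curtis"
    outlier_quantile: float = 0.9
    seed: int = 0
    #: convert counts to per-sample relative abundances before embedding
    relative: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.outlier_quantile < 1:
            raise ValueError("outlier_quantile must be in (0, 1)")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")


@dataclass
class EmbeddingResult:
    taxon_ids: list[str]
    coords: np.ndarray
    cluster_label: np.ndarray  # -1 = noise
    outlier_score: np.ndarray
    is_outlier: np.ndarray
    config: EmbeddingConfig | None = None

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.cluster_label) - {-1}))

    def to_frame(self) -> pd.DataFrame:
        coord_cols = {"x": self.coords[:, 0], "y": self.coords[:, 1]}
        for d in range(2, self.coords.shape[1]):
            coord_cols[f"dim{d + 1}"] = self.coords[:, d]
        return pd.DataFrame(
            {
                "taxon_id": self.taxon_ids,
                **coord_cols,
                "cluster_label": self.cluster_label,
                "outlier_score": self.outlier_score,
                "is_outlier": self.is_outlier,
            }
        )


def embed_and_cluster(
    table: AbundanceTable, config: EmbeddingConfig | None = None
) -> EmbeddingResult:
    """Embed taxa with UMAP and cluster the embedding with HDBSCAN.

    Deterministic given ``config.seed`` (UMAP runs single-threaded when
    seeded). Raises when the table has fewer taxa than ``n_neighbors``
    requires.
    """
    import umap  # deferred: numba compilation makes this import heavy

    config = config or EmbeddingConfig()
    if table.n_taxa <= config.n_neighbors:
        raise ValueError(
            f"n_taxa={table.n_taxa} must exceed n_neighbors="
            f"{config.n_neighbors}; lower n_neighbors"
        )
    x = table.counts.astype(float)
    if config.relative:
        totals = x.sum(axis=0, keepdims=True)
        totals[totals == 0] = 1.0
        x = x / totals

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="n_jobs value 1 overridden")
        reducer = umap.UMAP(
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            n_components=config.n_components,
            metric=_metric(config.input_metric),
            output_metric=_metric(config.output_metric),
            random_state=config.seed,
        )
        coords = reducer.fit_transform(x)

    dist = pairwise_distances(coords, metric=_metric(config.hdb_metric))
    dist = np.abs((dist + dist.T) / 2.0)
    np.fill_diagonal(dist, 0.0)
    if config.hdb_min_cluster_size > table.n_taxa:
        labels = np.full(table.n_taxa, -1)  # no cluster can form
    else:
        labels = HDBSCAN(
            min_cluster_size=config.hdb_min_cluster_size,
            min_samples=config.hdb_min_samples,
            metric="precomputed",
            copy=True,
        ).fit_predict(dist)

    scores = glosh_scores(
        dist,
        min_samples=config.hdb_min_samples,
        min_cluster_size=config.hdb_min_cluster_size,
    )
    threshold = np.quantile(scores, config.outlier_quantile)
    is_outlier = scores > threshold
    return EmbeddingResult(
        taxon_ids=list(table.taxon_ids),
        coords=np.asarray(coords, dtype=float),
        cluster_label=np.asarray(labels, dtype=int),
        outlier_score=scores,
        is_outlier=is_outlier,
        config=config,
    )


def export_clusters(result: EmbeddingResult, path: str | Path) -> None:
    """Write per-taxon embedding coordinates, labels and outlier flags.

    Column order: taxon_id, x, y[, dim3...], cluster_label,
    outlier_score, is_outlier.
    """
    result.to_frame().to_csv(path, index=False)
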