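"""End-to-end pipeline: filter -> SparCC -> embed -> network -> analyses.

A single :class:`PipelineConfig` drives the whole run; every stage seed
derives deterministically from the global seed, so identical configs
yield identical artifacts. Artifacts are written as each stage
completes, so a failure partway through leaves the finished ones on
disk and reports which stage broke.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import balance as balance_mod
from . import centrality as centrality_mod
from . import communities as communities_mod
from . import percolation as percolation_mod
from . import topology as topology_mod
from .abundance import AbundanceTable, filter_low_abundance, read_abundance
from .embedding import EmbeddingConfig, embed_and_cluster, export_clusters
from .network import build_network, export_network
from .sparcc import SparccConfig, pvalues, run_sparcc
from .synthetic import CommunitySpec, generate_community, generate_sparse_basis

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_sparcc"]

logger = logging.getLogger("occnet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    input_path: str | Path | None = None
    output_dir: str | Path = "occnet_out"
    seed: int = 0
    log_level: str = "INFO"
    # filtering
    filter_input: bool = True
    min_total: float = 5
    remove_unique: bool = True
    # stages
    sparcc: SparccConfig = field(default_factory=SparccConfig)
    compute_pvalues: bool = True
    embed: bool = True
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    # network construction
    include_rule: str = "auto"
    alpha: float = 0.05
    min_abs_corr: float = 0.0
    # analyses
    sw_replicates: int = 50
    percolation_strategy: str = "degree"
    percolation_step: float = 0.1

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sparcc = SparccConfig(**raw.pop("sparcc", {}))
        embedding = EmbeddingConfig(**raw.pop("embedding", {}))
        return cls(sparcc=sparcc, embedding=embedding, **raw)

    def stage_seeds(self) -> dict[str, int]:
        names = ("sparcc", "pvalues", "embedding", "topology", "percolation", "louvain")
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {
            n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, seqs)
        }


def run_pipeline(
    config: PipelineConfig, table: AbundanceTable | None = None
) -> dict:
    """Run every stage and write the report bundle into ``output_dir``.

    Returns a dict of artifact paths plus the aggregated summary. Either
    ``config.input_path`` or an in-memory ``table`` must be provided.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    seeds = config.stage_seeds()
    artifacts: dict = {"output_dir": str(outdir)}

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s: start", name)
                out = fn()
                logger.info("stage %s: done", name)
                return out
            except Exception as exc:  # noqa: BLE001 - report the stage
                logger.error("stage %s: FAILED: %s", name, exc)
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return deco

    try:
        logger.info(
            "occnet pipeline | python %s | numpy %s | seed %d | seeds %s",
            platform.python_version(), np.__version__, config.seed, seeds,
        )
        logger.info("config: %s", dataclasses.asdict(config))

        @stage("input")
        def _table() -> AbundanceTable:
            if table is not None:
                return table
            if config.input_path is None:
                raise ValueError("no input table given")
            return read_abundance(config.input_path)

        data = _table

        @stage("filter")
        def _filtered():
            if not config.filter_input:
                return data, None
            filtered, report = filter_low_abundance(
                data, config.min_total, config.remove_unique
            )
            report.to_csv(outdir / "filter_report.csv", index=False)
            return filtered, report

        data, _ = _filtered

        @stage("sparcc")
        def _corr():
            cfg = replace(config.sparcc, seed=seeds["sparcc"])
            result = run_sparcc(data, cfg)
            if config.compute_pvalues:
                result.pvalues = pvalues(
                    data, result, replace(cfg, seed=seeds["pvalues"])
                )
            result.write(
                outdir / "corr.csv",
                (outdir / "pval.csv") if result.pvalues is not None else None,
            )
            return result

        corr = _corr
        artifacts["corr"] = str(outdir / "corr.csv")
        if corr.pvalues is not None:
            artifacts["pval"] = str(outdir / "pval.csv")

        clusters = None
        if config.embed:

            @stage("embedding")
            def _embedded():
                cfg = replace(config.embedding, seed=seeds["embedding"])
                result = embed_and_cluster(data, cfg)
                export_clusters(result, outdir / "clusters.csv")
                return result

            clusters = _embedded
            artifacts["clusters"] = str(outdir / "clusters.csv")

        @stage("network")
        def _net():
            net = build_network(
                corr,
                include_rule=config.include_rule,
                alpha=config.alpha,
                min_abs_corr=config.min_abs_corr,
                taxonomy=data.taxonomy,
            )
            if clusters is not None:
                net.set_node_attribute(
                    "hdbscan_label",
                    dict(zip(clusters.taxon_ids, map(int, clusters.cluster_label))),
                )
            return net

        net = _net

        @stage("communities")
        def _partition():
            part = communities_mod.louvain_partition(net, seed=seeds["louvain"])
            net.set_node_attribute("louvain_label", part)
            taxmap = (
                dict(zip(data.taxon_ids, data.taxonomy))
                if data.taxonomy is not None
                else None
            )
            report = communities_mod.subnetwork_metrics(
                net, part, taxonomy=taxmap, partition_source="louvain"
            )
            report.to_csv(outdir / "report.csv", index=False)
            return part, report

        partition, report = _partition
        artifacts["report"] = str(outdir / "report.csv")

        export_network(net, outdir / "net.graphml")
        artifacts["network"] = str(outdir / "net.graphml")

        @stage("topology")
        def _summary():
            return topology_mod.summarize(
                net, sw_replicates=config.sw_replicates, seed=seeds["topology"]
            )

        summary = _summary

        @stage("balance")
        def _census():
            census = balance_mod.triad_census(net)
            (outdir / "census.json").write_text(
                json.dumps(census.to_dict(), indent=2, default=float)
            )
            return census

        census = _census
        artifacts["census"] = str(outdir / "census.json")

        @stage("percolation")
        def _trace():
            trace = percolation_mod.percolate(
                net,
                strategy=config.percolation_strategy,
                step_fraction=config.percolation_step,
                seed=seeds["percolation"],
            )
            trace.records.to_csv(outdir / "trace.csv", index=False)
            return trace

        _trace
        artifacts["trace"] = str(outdir / "trace.csv")

        @stage("centrality")
        def _central():
            df = centrality_mod.centralities(net)
            df.to_csv(outdir / "centrality.csv")
            return df

        _central
        artifacts["centrality"] = str(outdir / "centrality.csv")

        summary_payload = {
            "seed": config.seed,
            "stage_seeds": seeds,
            "n_taxa": data.n_taxa,
            "n_samples": data.n_samples,
            "topology": summary.to_dict(),
            "balance": census.to_dict(),
            "n_louvain_communities": int(len(set(partition.values()))),
            "n_hdbscan_clusters": (
                clusters.n_clusters if clusters is not None else None
            ),
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary_payload, indent=2, default=_json_default)
        )
        artifacts["summary"] = str(outdir / "summary.json")
        artifacts["summary_data"] = summary_payload
        return artifacts
    finally:
        logger.removeHandler(handler)
        handler.close()


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating, float)):
        return None if not np.isfinite(value) else float(value)
    raise TypeError(f"not JSON serializable: {type(value)}")


def validate_sparcc(
    n_taxa: int = 50,
    n_samples: int = 200,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    depth: int = 10_000,
    n_strong: int = 10,
    strength: float = 0.8,
    config: SparccConfig | None = None,
    n_bins: int = 5,
) -> dict:
    """RMSE of SparCC estimates against a planted sparse basis.

    Regenerates the standard validation design (50 taxa x 200 samples,
    multinomial log-normal with ~10 strong planted pairs), runs SparCC
    with default parameters per seed, and reports the RMSE over all
    off-diagonal entries — overall, per seed, and binned by the absolute
    planted correlation.
    """
    per_seed = []
    bin_edges = np.linspace(0, 1, n_bins + 1)
    binned_sq: list[list[float]] = [[] for _ in range(n_bins)]
    for seed in seeds:
        basis = generate_sparse_basis(n_taxa, n_strong, strength, seed=seed)
        spec = CommunitySpec(
            n_taxa=n_taxa, n_samples=n_samples, depth=depth,
            basis_correlation=basis, seed=seed,
        )
        table, truth = generate_community(spec)
        cfg = replace(config or SparccConfig(), seed=seed)
        est = run_sparcc(table, cfg).correlations
        iu = np.triu_indices(n_taxa, k=1)
        err = est[iu] - truth[iu]
        per_seed.append(float(np.sqrt(np.mean(err**2))))
        which = np.clip(
            np.digitize(np.abs(truth[iu]), bin_edges[1:-1]), 0, n_bins - 1
        )
        for b in range(n_bins):
            binned_sq[b].extend((err[which == b] ** 2).tolist())
    binned = {
        f"[{bin_edges[b]:.1f},{bin_edges[b + 1]:.1f})": (
            float(np.sqrt(np.mean(binned_sq[b]))) if binned_sq[b] else float("nan")
        )
        for b in range(n_bins)
    }
    return {
        "per_seed_rmse": per_seed,
        "median_rmse": float(np.median(per_seed)),
        "rmse_by_abs_correlation": binned,
        "design": {
            "n_taxa": n_taxa, "n_samples": n_samples, "depth": depth,
            "n_strong": n_strong, "strength": strength, "seeds": list(seeds),
        },
    }
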