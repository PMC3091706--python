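"""End-to-end pipeline: data -> networks -> consensus -> null -> topology ->
clustering -> enrichment -> robustness, with a machine-readable manifest.

A single :class:`PipelineConfig` (loadable from YAML, overridable from the
command line) carries every parameter; a single master seed deterministically
derives independent substreams for simulation, the null model, decoy terms
and random node removal, so a run is byte-reproducible from its config.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io
from .consensus import intersect_networks
from .enrichment import EnrichmentParams, enrich_clusters, term_frequency
from .errors import ConfigurationError
from .mcl import MCLParams, filter_clusters, mcl
from .network import NetworkConfig, build_network, degree_distribution_fit, \
    network_precision, non_isolated_nodes
from .nullmodel import NullModelParams, null_intersection
from .synthetic import SyntheticSpec, matched_gene_sets, simulate_datasets
from .topology import CoreParams, extract_core, hub_removal, topology_profile

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


def _substream_seed(master_seed: int, label: str) -> int:
    """Stable per-stage integer seed derived from the master seed."""
    key = sum(ord(ch) * 31 ** i for i, ch in enumerate(label)) % (2 ** 16)
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run, paper defaults pre-filled."""

    # inputs: either dataset paths or a simulation
    dataset_paths: list[str] = field(default_factory=list)
    simulate: bool = False
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides
    annotation_path: str | None = None
    annotation_category: str | None = None
    n_decoy_terms: int = 20
    decoy_size_range: tuple[int, int] = (10, 30)

    # network construction
    pcc_threshold: float = 0.70
    use_absolute_pcc: bool = False

    # null model
    swap_multiplier: int = 4
    n_replicates: int = 200

    # clustering / enrichment
    inflation: float = 1.3
    min_cluster_size: int = 10
    max_term_size: int = 1500

    # core / robustness
    core_log_betweenness: float = 6.0
    core_degree: int = 15
    removal_k: int = 200

    output_dir: str = "coexnet_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.simulate:
            if len(self.dataset_paths) == 0:
                raise ConfigurationError(
                    "either dataset_paths or simulate=True is required"
                )
            for p in self.dataset_paths:
                if not Path(p).exists():
                    raise ConfigurationError(f"dataset path does not exist: {p}")
        if self.annotation_path and not Path(self.annotation_path).exists():
            raise ConfigurationError(
                f"annotation path does not exist: {self.annotation_path}"
            )
        # constructing the parameter objects validates the numeric ranges
        NetworkConfig(self.pcc_threshold, self.use_absolute_pcc)
        NullModelParams(self.swap_multiplier, self.n_replicates, self.seed)
        MCLParams(inflation=self.inflation,
                  min_cluster_size_for_enrichment=self.min_cluster_size)
        CoreParams(self.core_log_betweenness, self.core_degree)


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config file; keyword overrides win."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if isinstance(cfg.decoy_size_range, list):
        cfg.decoy_size_range = tuple(cfg.decoy_size_range)
    return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts + manifest.

    Returns the manifest dictionary. Any stage failure propagates with the
    stage recorded in the manifest written so far (partial outputs are kept
    on disk).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }
    stage = "setup"
    try:
        # ------------------------------------------------------------ data
        stage = "data"
        t0 = time.perf_counter()
        module_map: dict[str, str] = {}
        annot = None
        if config.simulate:
            spec = SyntheticSpec(
                **{**config.synthetic,
                   "seed": _substream_seed(config.seed, "simulate")}
            )
            datasets, module_map = simulate_datasets(spec)
            for d, expr in enumerate(datasets):
                io.write_expression_tsv(expr, out / f"dataset_{d}.tsv")
            io.write_ground_truth(module_map, out / "ground_truth.tsv")
            annot = matched_gene_sets(
                module_map,
                n_decoy_terms=config.n_decoy_terms,
                decoy_size_range=config.decoy_size_range,
                seed=_substream_seed(config.seed, "decoys"),
                all_genes=list(datasets[0].index),
                category=config.annotation_category,
            )
            io.write_gmt(annot, out / "annotation.gmt")
        else:
            datasets = [io.read_expression_tsv(p) for p in config.dataset_paths]
        if config.annotation_path:
            annot = io.read_gmt(
                config.annotation_path, category=config.annotation_category
            )
        manifest["stages"]["data"] = {
            "n_datasets": len(datasets),
            "genes_per_dataset": [int(d.shape[0]) for d in datasets],
            "samples_per_dataset": [int(d.shape[1]) for d in datasets],
            "n_planted_module_genes": len(module_map),
            "n_annotation_terms": len(annot) if annot is not None else 0,
        }
        _tick(stage, t0)

        # -------------------------------------------------- per-dataset nets
        stage = "network"
        t0 = time.perf_counter()
        net_cfg = NetworkConfig(config.pcc_threshold, config.use_absolute_pcc)
        nets = []
        net_stats = []
        for d, expr in enumerate(datasets):
            net = build_network(expr, net_cfg)
            nets.append(net)
            io.write_edge_list(net, out / f"network_{d}.tsv")
            entry = {
                "n_genes": len(non_isolated_nodes(net)),
                "n_nodes_total": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
            }
            try:
                entry["degree_fit"] = degree_distribution_fit(net)
            except Exception:
                entry["degree_fit"] = None
            if annot is not None:
                entry["precision"] = network_precision(net, annot)
            net_stats.append(entry)
        manifest["stages"]["network"] = {
            "pcc_threshold": config.pcc_threshold,
            "per_dataset": net_stats,
        }
        _tick(stage, t0)

        # --------------------------------------------------------- consensus
        stage = "consensus"
        t0 = time.perf_counter()
        cons = intersect_networks(nets)
        io.write_edge_list(cons.conserved, out / "conserved_network.tsv")
        manifest["stages"]["consensus"] = {
            "n_genes": cons.n_genes,
            "n_edges": cons.n_edges,
            "node_intersection_size": cons.node_intersection_size,
            "pairwise_overlaps": {
                f"{i}-{j}": v for (i, j), v in cons.pairwise_overlaps.items()
            },
        }
        if annot is not None and cons.n_genes > 0:
            manifest["stages"]["consensus"]["precision"] = network_precision(
                cons.conserved, annot
            )
        _tick(stage, t0)

        # -------------------------------------------------------- null model
        stage = "null_model"
        t0 = time.perf_counter()
        null_params = NullModelParams(
            swap_multiplier=config.swap_multiplier,
            n_replicates=config.n_replicates,
            seed=_substream_seed(config.seed, "null"),
        )
        null_res = null_intersection(nets, null_params)
        io.write_json(
            {
                "replicate_sizes": null_res.replicate_sizes,
                "null_mean": null_res.null_mean,
                "null_sd": null_res.null_sd,
                "observed": null_res.observed,
                "z_score": null_res.z_score,
            },
            out / "null_model.json",
        )
        manifest["stages"]["null_model"] = {
            "n_replicates": config.n_replicates,
            "null_mean": null_res.null_mean,
            "null_sd": null_res.null_sd,
            "observed": null_res.observed,
            "z_score": null_res.z_score,
        }
        _tick(stage, t0)

        # --------------------------------------------------- topology / core
        stage = "topology"
        t0 = time.perf_counter()
        profile = topology_profile(cons.conserved)
        profile.per_node.to_csv(out / "topology_per_node.tsv", sep="\t")
        io.write_json(profile.graph_level(), out / "topology_graph.json")
        core_params = CoreParams(config.core_log_betweenness, config.core_degree)
        core, hubs = extract_core(cons.conserved, core_params)
        io.write_edge_list(core, out / "core_network.tsv")
        manifest["stages"]["topology"] = {
            **profile.graph_level(),
            "core_n_genes": core.number_of_nodes(),
            "core_n_edges": core.number_of_edges(),
            "n_hubs": len(hubs),
        }
        _tick(stage, t0)

        # -------------------------------------------------------- clustering
        stage = "mcl"
        t0 = time.perf_counter()
        mcl_params = MCLParams(
            inflation=config.inflation,
            min_cluster_size_for_enrichment=config.min_cluster_size,
        )
        cluster_sets = {}
        for name, graph in (("conserved", cons.conserved), ("core", core)):
            if graph.number_of_nodes() == 0:
                continue
            cs = mcl(graph, mcl_params)
            cluster_sets[name] = cs
            io.write_clusters_tsv(cs, out / f"clusters_{name}.tsv")
            io.write_clusters_mcl(cs, out / f"clusters_{name}.mcl")
            manifest["stages"].setdefault("mcl", {})[name] = {
                "n_clusters": len(cs.clusters),
                "n_singletons": cs.n_singletons,
                "largest_cluster": max(cs.sizes) if cs.sizes else 0,
                "converged": cs.converged,
                "n_iterations": cs.n_iterations,
            }
        _tick(stage, t0)

        # -------------------------------------------------------- enrichment
        stage = "enrichment"
        t0 = time.perf_counter()
        if annot is not None and "conserved" in cluster_sets:
            enr_params = EnrichmentParams(
                max_term_size=config.max_term_size,
                min_cluster_size=config.min_cluster_size,
            )
            table = enrich_clusters(
                cluster_sets["conserved"], annot, enr_params
            )
            table.to_csv(out / "enrichment_conserved.tsv", sep="\t", index=False)
            top = table[table["is_top_term"]] if not table.empty else table
            freq = term_frequency(
                set(non_isolated_nodes(cons.conserved)), annot, top_k=10
            )
            freq.to_csv(out / "term_frequency_conserved.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {
                "n_scored_pairs": int(len(table)),
                "n_clusters_enriched": int(table["cluster"].nunique())
                if not table.empty else 0,
                "top_terms": {
                    str(r.cluster): {"term": r.term, "log_odds": float(r.log_odds)}
                    for r in top.itertuples()
                } if not table.empty else {},
            }
        _tick(stage, t0)

        # -------------------------------------------------------- robustness
        stage = "robustness"
        t0 = time.perf_counter()
        n_nodes = cons.conserved.number_of_nodes()
        if n_nodes > 2:
            k = min(config.removal_k, n_nodes - 1)
            if k < config.removal_k:
                log.warning(
                    "removal_k=%d >= network size %d; clamped to %d",
                    config.removal_k, n_nodes, k,
                )
            every = max(1, k // 20)
            targeted = hub_removal(
                cons.conserved, k=k, mode="targeted",
                recompute_metrics_every=every,
            )
            rand = hub_removal(
                cons.conserved, k=k, mode="random",
                seed=_substream_seed(config.seed, "robustness"),
                recompute_metrics_every=every,
            )
            targeted.steps.to_csv(
                out / "robustness_targeted.tsv", sep="\t", index=False
            )
            rand.steps.to_csv(out / "robustness_random.tsv", sep="\t", index=False)
            manifest["stages"]["robustness"] = {
                "k": k,
                "targeted_final_cpl": float(
                    targeted.steps["characteristic_path_length"].iloc[-1]
                ),
                "random_final_cpl": float(
                    rand.steps["characteristic_path_length"].iloc[-1]
                ),
                "targeted_final_components": int(
                    targeted.steps["n_components"].iloc[-1]
                ),
                "random_final_components": int(rand.steps["n_components"].iloc[-1]),
            }
        _tick(stage, t0)

        manifest["seed"] = config.seed
        io.write_json(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        manifest["failed_stage"] = stage
        io.write_json(manifest, out / "manifest.json")
        raise


def _tick(stage: str, t0: float) -> None:
    log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
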