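"""End-to-end orchestration of the regional proteome analysis.

Stage order mirrors the study: quantify differential abundance, compute
differential stability and co-abundance modules, build and cluster the
weighted regional PPI networks, extract the stable core, correlate with
the connectome, and run ontology enrichment.  Every stage's outputs are
written before the next begins, and a machine-readable run report
collects the headline quantities of each stage.  Given the same
configuration (including seed) the report is byte-identical between
runs.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from psdnet import connectome as conn
from psdnet import core, enrichment, io, network, quantify, signatures, simulate

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("psdnet")


@dataclass
class RunConfig:
    """All thresholds, paths and the seed for one pipeline run.

    Thresholds default to the analysis rules: pairwise BH-adjusted
    ``alpha`` 0.05, fold threshold 1.5 (1.3 with the reciprocal 0.667
    bound is the documented alternative), >= 2 unique peptides,
    connectome selection at r^2 >= 0.6, stability ``max_score`` 2 of 7
    regions, and elimination threshold 0.01.
    """

    outdir: str = "psdnet_out"
    seed: int = 0
    alpha: float = 0.05
    fold_threshold: float = 1.5
    min_peptides: int = 2
    de_mode: str = "all"
    ds_cutoff: float | None = None
    k_range: tuple = (2, 10)
    r2_threshold: float = 0.6
    max_score: int = 2
    alpha_elim: float = 0.01
    normalize: bool = True
    reference_run: str | None = None
    # input paths; empty string means "simulate this input"
    abundance_path: str = ""
    edges_path: str = ""
    connectome_path: str = ""
    obo_path: str = ""
    annotations_path: str = ""
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.max_score < 0:
            raise ValueError("max_score must be >= 0")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)

    def sim_config(self) -> simulate.SimConfig:
        params = dict(self.sim)
        params.setdefault("seed", self.seed)
        for key in ("region_group", "region_names"):
            if key in params:
                params[key] = tuple(params[key])
        return simulate.SimConfig(**params)


def _stage(name: str, report: dict, t0: float) -> None:
    log.info("stage %-11s done in %.2fs", name, time.perf_counter() - t0)
    report["stages_completed"] = report.get("stages_completed", []) + [name]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report.

    A stage failure aborts the run with an error naming the stage;
    outputs of completed stages remain on disk.
    """
    report: dict = {}
    try:
        return _run_pipeline(config, report)
    except Exception as exc:
        done = report.get("stages_completed", [])
        current = (["inputs", "quantify", "signatures", "network", "core",
                    "connectome", "enrichment"] + [None])[len(done)]
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc


def _run_pipeline(config: RunConfig, report: dict) -> dict:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = io.config_hash(config)
    report["seed"] = config.seed
    report["config"] = dataclasses.asdict(config)
    report["config"]["k_range"] = list(config.k_range)

    # ---- inputs: simulate or ingest -------------------------------------
    t0 = time.perf_counter()
    truth = None
    if config.abundance_path:
        tensor = io.read_abundance(config.abundance_path)
        edges = io.read_edges(config.edges_path)
        connectome_matrix = io.read_connectome(config.connectome_path)
        dag = io.read_obo(config.obo_path)
        direct_annotations = io.read_annotations(config.annotations_path)
    else:
        sim_cfg = config.sim_config()
        arts = simulate.simulate_all(sim_cfg)
        tensor, truth = arts["tensor"], arts["truth"]
        edges, connectome_matrix = arts["edges"], arts["connectome"]
        dag, direct_annotations = arts["ontology"], arts["annotations"]
        io.write_abundance(tensor, out / "abundance.tsv", cfg_hash)
        io.write_edges(edges, out / "ppi_edges.tsv", cfg_hash)
        io.write_connectome(connectome_matrix, out / "connectome.csv", cfg_hash)
        io.write_obo(dag, out / "ontology.obo", cfg_hash)
        io.write_annotations(direct_annotations, out / "annotations.tsv", cfg_hash)
        io.write_table(truth.to_frame(), out / "ground_truth.tsv", cfg_hash)
    report["n_proteins"] = len(tensor.proteins)
    report["n_regions"] = len(tensor.regions)
    report["n_replicates"] = len(tensor.replicates)
    _stage("inputs", report, t0)

    # ---- quantify -------------------------------------------------------
    t0 = time.perf_counter()
    if config.normalize:
        tensor = quantify.normalize_runs(tensor, config.reference_run)
    gstats = quantify.group_stats(tensor)
    tests = quantify.anova_and_pairwise(tensor)
    de = quantify.de_filter(
        tensor,
        fold_threshold=config.fold_threshold,
        alpha=config.alpha,
        min_peptides=config.min_peptides,
        mode=config.de_mode,
        stats_cache={"raw_means": gstats["raw_means"], "pairwise": tests["pairwise"]},
    )
    z = gstats["arcsinh_means"].apply(
        lambda row: pd.Series(quantify.zscore_profile(row.to_numpy())[0], index=row.index),
        axis=1,
    )
    io.write_table(de.table, out / "de_table.tsv", cfg_hash)
    io.write_json({"counts": de.counts}, out / "de_counts.json", cfg_hash)
    report["de_counts"] = de.counts
    report["frac_de"] = de.n_de / len(tensor.proteins)
    _stage("quantify", report, t0)

    # ---- signatures -----------------------------------------------------
    t0 = time.perf_counter()
    ds = signatures.differential_stability(tensor)
    high_ds = signatures.select_high_ds(ds, config.ds_cutoff)
    raw_means = gstats["raw_means"]
    kinfo = signatures.choose_k(raw_means, k_range=config.k_range)
    modules = signatures.cut_dendrogram(kinfo["linkage"], kinfo["K"], raw_means.index)
    presence = z > 0  # "positive abundance": above the protein's regional average
    links = signatures.circos_links(modules, presence)
    io.write_table(ds, out / "ds_table.tsv", cfg_hash)
    io.write_table(
        modules.rename("module").reset_index().rename(columns={"index": "protein_id"}),
        out / "ppm_assignment.tsv",
        cfg_hash,
    )
    io.write_table(links, out / "circos_links.tsv", cfg_hash)
    io.write_circos(links, tensor.regions, out / "circos", cfg_hash)
    io.write_newick(
        signatures.linkage_to_newick(kinfo["clustering"]["col_linkage"], tensor.regions),
        out / "region_dendrogram.nwk",
    )
    ranked = raw_means.copy()
    ranked["module"] = modules
    io.write_table(
        ranked.reset_index().rename(columns={"index": "protein_id"}),
        out / "module_abundance.tsv",
        cfg_hash,
    )
    report["ds_min"] = float(ds["avg_cor"].min())
    report["ds_max"] = float(ds["avg_cor"].max())
    report["n_high_ds"] = len(high_ds)
    report["ppm_count"] = int(kinfo["K"])
    _stage("signatures", report, t0)

    # ---- ppi network ----------------------------------------------------
    t0 = time.perf_counter()
    graph = network.build_network(edges, set(tensor.proteins))
    regional = network.weight_edges(graph, raw_means)
    clustered = network.cluster_all_regions(regional)
    partitions = clustered["partitions"]
    for region, part in partitions.items():
        io.write_table(part.to_frame(), out / f"partition_{region}.tsv", cfg_hash)
    io.write_gexf(regional[tensor.regions[0]], out / "network.gexf",
                  partitions[tensor.regions[0]], regional_weights=regional)
    io.write_table(clustered["summary"], out / "network_summary.tsv", cfg_hash)
    report["n_network_nodes"] = graph.number_of_nodes()
    report["n_network_edges"] = graph.number_of_edges()
    report["modularity"] = {r: p.Q for r, p in partitions.items()}
    report["n_communities"] = {r: p.n_communities for r, p in partitions.items()}
    _stage("network", report, t0)

    # ---- stable core ----------------------------------------------------
    t0 = time.perf_counter()
    edge_list = sorted(tuple(sorted(e)) for e in graph.edges)
    scores = core.stability_scores(partitions, edge_list)
    stable = core.select_stable(scores, max_score=config.max_score)
    io.write_table(scores, out / "stability_scores.tsv", cfg_hash)
    if stable.partition is not None:
        io.write_table(stable.partition.to_frame(), out / "stable_partition.tsv", cfg_hash)
        io.write_gexf(stable.graph, out / "stable_network.gexf", stable.partition)
        overlap = core.module_overlap(
            stable.partition, dict(zip(modules.index, modules)), set(tensor.proteins)
        )
        io.write_table(overlap, out / "stable_ppm_overlap.tsv", cfg_hash)
        report["stable_n_communities"] = stable.partition.n_communities
        report["stable_min_overlap_p"] = float(overlap["p"].min()) if len(overlap) else 1.0
    report["stable_fraction"] = stable.stable_fraction
    report["stable_n_edges"] = stable.n_edges
    _stage("core", report, t0)

    # ---- connectome -----------------------------------------------------
    t0 = time.perf_counter()
    vector = conn.connectivity_vector(connectome_matrix)
    cors = conn.correlate_proteins(raw_means, vector, config.r2_threshold)
    cc = conn.correlation_cluster(raw_means, connectome_matrix)
    io.write_table(cors, out / "connectome_correlation.tsv", cfg_hash)
    io.write_table(cc["matrix"], out / "connectome_cluster_matrix.tsv", cfg_hash, index=True)
    io.write_newick(
        signatures.linkage_to_newick(cc["linkage"], list(cc["matrix"].index)),
        out / "connectome_dendrogram.nwk",
    )
    report["n_connectome_selected"] = int(cors["selected"].sum())
    _stage("connectome", report, t0)

    # ---- enrichment -----------------------------------------------------
    t0 = time.perf_counter()
    propagated = enrichment.propagate_annotations(dag, direct_annotations)
    module_sets = {int(m): set(modules.index[modules == m]) for m in sorted(modules.unique())}
    ppm_enrich = enrichment.enrich_clusters(
        module_sets, dag, propagated, set(tensor.proteins), alpha_elim=config.alpha_elim
    )
    io.write_table(ppm_enrich["top_terms"], out / "ppm_enrichment_top.tsv", cfg_hash)
    network_universe = set(graph.nodes)
    cluster_top: dict[str, int] = {}
    if stable.partition is not None:
        stable_enrich = enrichment.enrich_clusters(
            stable.partition.communities(), dag, propagated, network_universe,
            alpha_elim=config.alpha_elim,
        )
        io.write_table(stable_enrich["top_terms"], out / "stable_enrichment_top.tsv", cfg_hash)
        cluster_top["stable"] = len(stable_enrich["top_terms"])
    for region, part in partitions.items():
        reg_enrich = enrichment.enrich_clusters(
            part.communities(), dag, propagated, network_universe,
            alpha_elim=config.alpha_elim,
        )
        io.write_table(reg_enrich["top_terms"], out / f"enrichment_top_{region}.tsv", cfg_hash)
        cluster_top[region] = len(reg_enrich["top_terms"])
    report["enriched_cluster_tables"] = cluster_top
    report["ppm_top_terms"] = {
        str(row["cluster"]): row["term"] for _, row in ppm_enrich["top_terms"].iterrows()
    }
    _stage("enrichment", report, t0)

    io.write_json(report, out / "run_report.json", cfg_hash)
    return report
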