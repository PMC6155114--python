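"""End-to-end pipeline: tables -> network -> clusters -> predictions.

Stage order: normalise to relative abundance; prevalence-filter; Spearman
matrix with BH-FDR; network deconvolution; RMT threshold scan; signed
network; multi-resolution clustering with hierarchy, hubs and roles;
enrichment and DUF prediction; negative-edge and (optional) environment
analyses. One run seed drives every stochastic stage through a fixed
seed-derivation rule, so a run is reproducible end to end.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import stage_seed
from .annotate import cluster_enrichment, env_gene_links, predict_duf_functions, predictions_frame
from .clusters import (
    build_hierarchy,
    cluster_hubs,
    dominant_clusters,
    inter_cluster_connectivity,
    membership_frame,
    multires_scan,
    node_roles,
)
from .correlation import DeconvolutionParams, deconvolve, spearman_matrix
from .data_model import (
    classify_prevalence,
    filter_excluded,
    read_abundance,
    read_env,
    read_metadata,
    relative_abundance,
)
from .network import (
    build_network,
    edge_partition,
    er_null,
    negative_edge_summary,
    sign_counts,
    subnetwork,
    topology_summary,
    write_edge_list,
    write_graphml,
)
from .rmt import scan_threshold


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All run parameters; defaults follow a 45-sample survey design."""

    abundance: str = ""
    metadata: str = ""
    env: str | None = None
    outdir: str = "run"
    min_prevalence: int = 25
    min_abundance: float = 0.0
    alpha: float = 1.0
    beta: float = 0.99
    rescale_deconvolved: bool = True
    threshold: float | None = None  # fixed cutoff; None = choose by RMT scan
    grid_start: float = 0.30
    grid_stop: float = 0.99
    grid_step: float = 0.01
    min_eigen: int = 100
    test_alpha: float = 0.001
    q_max: float = 0.05
    resolutions: list[float] = field(default_factory=lambda: list(range(1, 16)))
    min_size: int = 10
    min_within: int = 3
    seed: int = 0

    def validate(self, n_samples: int | None = None) -> None:
        DeconvolutionParams(self.alpha, self.beta).validate()
        if not 0.0 < self.q_max <= 1.0:
            raise ValueError("q_max must lie in (0, 1]")
        if self.min_prevalence < 0:
            raise ValueError("min_prevalence must be non-negative")
        if n_samples is not None and self.min_prevalence > n_samples:
            raise ValueError(
                f"min_prevalence {self.min_prevalence} exceeds n_samples {n_samples}"
            )
        if self.grid_step <= 0 or self.grid_stop <= self.grid_start:
            raise ValueError("invalid RMT grid")
        if self.threshold is not None and not 0.0 < self.threshold < 1.0:
            raise ValueError("fixed threshold must lie in (0, 1)")
        if len(self.resolutions) < 2:
            raise ValueError("need >= 2 resolutions for a hierarchy")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.grid_start, self.grid_stop + self.grid_step / 2, self.grid_step),
            6,
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage from TSV inputs; write artifacts to ``config.outdir``."""
    table = read_abundance(config.abundance)
    metadata = read_metadata(config.metadata)
    env = read_env(config.env) if config.env else None
    return run_from_tables(table, metadata, env, config)


def run_from_tables(table, metadata, env, config: PipelineConfig) -> dict:
    config.validate(n_samples=table.n_samples)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"metagenet {__version__}",
        f"python {sys.version.split()[0]}",
        f"seed {config.seed}",
        "config " + json.dumps(asdict(config), sort_keys=True),
    ]

    def _stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
        log.append(f"stage {name}: ok")
        return result

    rel = _stage("relative_abundance", lambda: relative_abundance(table))
    prevalence = _stage(
        "classify_prevalence",
        lambda: classify_prevalence(rel, config.min_prevalence, config.min_abundance),
    )
    filtered = _stage("prevalence_filter", lambda: filter_excluded(rel, prevalence))
    corr = _stage("spearman", lambda: spearman_matrix(filtered))
    params = DeconvolutionParams(config.alpha, config.beta)
    corr.deconvolved_rho = _stage("deconvolve", lambda: deconvolve(corr.rho, params))

    M = corr.deconvolved_rho
    if config.rescale_deconvolved:
        peak = float(np.abs(M).max())
        if peak > 0:
            M = M / peak  # sign/order preserving; makes the RMT grid scale-free
    if config.threshold is None:
        scan = _stage(
            "rmt_threshold",
            lambda: scan_threshold(
                M,
                grid=config.grid(),
                min_eigen=config.min_eigen,
                test_alpha=config.test_alpha,
                seed=stage_seed(config.seed, "rmt"),
            ),
        )
        chosen = scan.chosen_threshold
    else:
        scan = None
        chosen = float(config.threshold)
    net = _stage(
        "build_network",
        lambda: build_network(
            corr, chosen, config.q_max,
            metadata=metadata, prevalence=prevalence, weights=M,
        ),
    )
    if net.number_of_nodes() == 0:
        raise StageError("build_network", RuntimeError("no edges pass the threshold + FDR rule"))

    cseed = stage_seed(config.seed, "cluster")
    clusterings = _stage("multires_scan", lambda: multires_scan(net, config.resolutions, cseed))
    base = clusterings[0]
    dom, loose = dominant_clusters(base, config.min_size)
    hierarchy = _stage("build_hierarchy", lambda: build_hierarchy(clusterings))
    conn = inter_cluster_connectivity(net, base)
    hubs, hub_table = (
        cluster_hubs(net, base, dom) if dom else ({}, pd.DataFrame())
    )
    roles = node_roles(net, base, hubs)
    enrichment = _stage("enrichment", lambda: cluster_enrichment(base, metadata, dom))
    predictions = _stage(
        "duf_prediction",
        lambda: predict_duf_functions(
            net, base, roles, enrichment, dom,
            min_within=config.min_within, q_max=config.q_max,
        ),
    )
    neg = negative_edge_summary(net)
    topo = topology_summary(net)
    partition = edge_partition(net)
    _, null_hist = er_null(topo.n_nodes, topo.n_edges, seed=stage_seed(config.seed, "null"))
    env_result = (
        _stage("env_links", lambda: env_gene_links(env, filtered, base, config.q_max))
        if env is not None and len(env)
        else None
    )

    check_conservation(net, base, roles, partition)

    prev_counts = {"core": 0, "noncore": 0, "excluded": 0}
    for pc in prevalence.values():
        prev_counts[pc.label.value] += 1

    summary = {
        "seed": config.seed,
        "n_genes_input": table.n_genes,
        "n_samples": table.n_samples,
        "prevalence_counts": prev_counts,
        "chosen_threshold": chosen,
        "threshold_source": "rmt_scan" if scan is not None else "fixed",
        "n_nodes": topo.n_nodes,
        "n_edges": topo.n_edges,
        "n_positive": topo.n_positive,
        "n_negative": topo.n_negative,
        "edge_partition": partition,
        "density": topo.density,
        "clustering_mean_local": topo.clustering_mean_local,
        "clustering_transitivity": topo.clustering_transitivity,
        "diameter_lcc": topo.diameter_lcc,
        "powerlaw_r2": topo.powerlaw_r2,
        "powerlaw_slope": topo.powerlaw_slope,
        "er_null_degree_hist": {str(k): v for k, v in null_hist.items()},
        "cluster_counts_per_resolution": {
            str(c.resolution): c.n_clusters for c in clusterings
        },
        "n_dominant_clusters": len(dom),
        "n_loose_nodes": len(loose),
        "n_merge_events": len(hierarchy.merges),
        "hub_genes": {str(c): g for c, g in sorted(hubs.items())},
        "negative_endpoint_classes": neg.endpoint_class_counts,
        "n_duf_nodes": sum(1 for v in net.nodes if net.nodes[v].get("is_duf")),
        "duf_predictions": {
            p.gene: p.predicted_categories[0] if p.predicted_categories else ""
            for p in predictions
        },
        "n_env_links": int(len(env_result["links"])) if env_result else 0,
    }

    # ------------------------------------------------------------- artifacts
    pd.DataFrame(
        [(g, pc.label.value, pc.presence) for g, pc in prevalence.items()],
        columns=["gene", "prevalence", "presence"],
    ).to_csv(out / "prevalence.tsv", sep="\t", index=False)
    corr.to_long().to_csv(out / "correlations.tsv", sep="\t", index=False)
    if scan is not None:
        scan.to_frame().to_csv(out / "rmt_scan.tsv", sep="\t", index=False)
    write_edge_list(net, out / "edges.tsv")
    write_graphml(_graphml_ready(net, base), out / "network.graphml")
    membership_frame(clusterings).to_csv(out / "clusters.tsv", sep="\t", index=False)
    hierarchy.to_json(out / "hierarchy.json")
    (out / "hierarchy.txt").write_text(hierarchy.to_text() + "\n")
    conn.to_csv(out / "cluster_connectivity.tsv", sep="\t", index_label="cluster")
    if len(hub_table):
        hub_table.to_csv(out / "hubs.tsv", sep="\t", index=False)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    predictions_frame(predictions).to_csv(out / "duf_predictions.tsv", sep="\t", index=False)
    neg.negative_degree.rename_axis("gene").reset_index().to_csv(
        out / "negative_degree.tsv", sep="\t", index=False
    )
    if env_result is not None:
        env_result["links"].to_csv(out / "env_links.tsv", sep="\t", index=False)
        env_result["cluster_concentration"].to_csv(
            out / "env_cluster_concentration.tsv", sep="\t", index=False
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return summary


def _graphml_ready(net, clustering):
    g = net.copy()
    for v in g.nodes:
        g.nodes[v]["cluster"] = int(clustering.membership[v])
    return g


def check_conservation(net, clustering, roles, partition: dict[str, int]) -> None:
    """Exact bookkeeping identities every run must satisfy.

    Sign counts sum to the edge count; the prevalence edge partition sums to
    the edge count; within/between degree sums obey the handshake lemma; the
    membership is a partition of the node set.
    """
    m = net.number_of_edges()
    pos, negc = sign_counts(net)
    if pos + negc != m:
        raise AssertionError("sign counts do not sum to edge count")
    if sum(partition.values()) != m:
        raise AssertionError("edge partition does not sum to edge count")
    within = sum(1 for a, b in net.edges
                 if clustering.membership[a] == clustering.membership[b])
    kw_sum = sum(r.within_degree for r in roles.values())
    kb_sum = sum(r.between_degree for r in roles.values())
    if kw_sum != 2 * within or kb_sum != 2 * (m - within):
        raise AssertionError("role degree handshake violated")
    if set(clustering.membership) != set(net.nodes):
        raise AssertionError("cluster membership is not a partition of the nodes")


def render_report(run_dir: str | Path) -> str:
    """Human-readable digest of a completed run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json under {run_dir}")
    s = json.loads(summary_path.read_text())
    lines = [
        "Gene correlation network report",
        "=" * 33,
        f"genes in: {s['n_genes_input']}  samples: {s['n_samples']}",
        "prevalence: " + ", ".join(f"{k}={v}" for k, v in s["prevalence_counts"].items()),
        f"threshold (RMT): {s['chosen_threshold']}",
        f"network: {s['n_nodes']} nodes, {s['n_edges']} edges "
        f"({s['n_positive']} positive, {s['n_negative']} negative)",
        "edge partition: " + ", ".join(f"{k}={v}" for k, v in s["edge_partition"].items()),
        f"dominant clusters: {s['n_dominant_clusters']} "
        f"(loose nodes: {s['n_loose_nodes']}); merges in hierarchy: {s['n_merge_events']}",
        "",
        "Hubs",
        "----",
    ]
    if s["hub_genes"]:
        for c, g in sorted(s["hub_genes"].items(), key=lambda kv: int(kv[0])):
            lines.append(f"  cluster {c}: {g}")
    else:
        lines.append("  none")
    lines += ["", "Negative edges", "--------------"]
    if s["n_negative"] == 0:
        lines.append("  none")
    else:
        lines.append("  endpoint classes: " + ", ".join(
            f"{k}={v}" for k, v in s["negative_endpoint_classes"].items()))
    lines += ["", "DUF predictions", "---------------"]
    if s["duf_predictions"]:
        for g, cat in sorted(s["duf_predictions"].items()):
            lines.append(f"  {g}: {cat or '(no enriched category)'}")
    else:
        lines.append("  none")
    hier = run_dir / "hierarchy.txt"
    if hier.exists():
        lines += ["", "Cluster hierarchy", "-----------------", hier.read_text().rstrip()]
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
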