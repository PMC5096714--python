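"""End-to-end orchestration: quantify -> compare -> enrich -> network ->
topology -> steiner, with a declarative JSON config and a run report.

Every stage writes its intermediate artifact (TSV/JSON) into the output
directory, and every number in the report is recomputable from those files.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx

from . import enrich as en
from . import interactome as ia
from . import quantify as qt
from . import steiner as st
from . import topology as tp

logger = logging.getLogger("proteonet")

__all__ = ["RunConfig", "run_pipeline"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the study constants: fold 2, confidence cutoff
    0.63 (medium; 0.73 = high), context consensus 2 sources, hub degree 10,
    bottleneck betweenness 0.3, enrichment alpha 0.05 with >= 3 genes per
    term, kappa threshold 0.35 with group membership 2.
    """

    quant_a: str
    quant_b: str
    cell_line_a: str = "A549"
    cell_line_b: str = "SW900"
    edges: str | None = None
    source_manifest: str | None = None
    gmt: str | None = None
    outdir: str = "proteonet_out"
    seed: int = 0
    # thresholds
    fold_threshold: float = 2.0
    score_cutoff: float = 0.63
    min_sources: int = 2
    degree_cut: int = 10
    bc_cut: float = 0.3
    alpha: float = 0.05
    min_genes: int = 3
    use_fdr: bool = False
    kappa_threshold: float = 0.35
    membership: int = 2
    # steiner
    beta: float = 1.0
    cost_mode: str = "log"
    solver: str = "auto"
    merge_mode: str = "detected"
    keep_interactor_edges: bool = False
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 <= self.score_cutoff <= 1:
            raise ValueError("score_cutoff must be in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 <= self.bc_cut <= 1:
            raise ValueError("bc_cut must be in [0, 1]")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                logger.error("stage %s: failed", name)
                raise RuntimeError(f"pipeline stage {name!r} failed") from None
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def _fold_labels(
    profile: qt.ProteomeProfile,
    part: qt.PartitionResult,
    diff_by_acc: dict[str, qt.DifferentialRecord],
    own_specific: frozenset[str],
) -> dict[str, str]:
    labels = {}
    for acc in profile.accessions:
        if acc in own_specific:
            labels[acc] = "specific"
        elif acc in part.shared:
            labels[acc] = diff_by_acc[acc].label
        else:
            labels[acc] = "none"
    return labels


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    report: dict = {"schema_version": CONFIG_SCHEMA_VERSION}

    # --- quantify + partition + differential -------------------------------
    profiles = {}
    for key, path, name in (
        ("a", config.quant_a, config.cell_line_a),
        ("b", config.quant_b, config.cell_line_b),
    ):
        table = qt.read_quant_table(path)
        logger.info("quant %s: %d rows", name, len(table))
        profiles[key] = qt.profile_from_table(table, name, merge_mode=config.merge_mode)
    profile_a, profile_b = profiles["a"], profiles["b"]

    part = qt.partition(profile_a, profile_b)
    qt.write_partition_report(part, outdir / "partition.tsv", outdir / "partition.json")
    report["venn"] = part.counts

    diff = qt.compare_profiles(profile_a, profile_b, threshold=config.fold_threshold)
    qt.write_differential_table(diff, outdir / "differential.tsv")
    n_over = sum(r.label == "over" for r in diff)
    n_under = sum(r.label == "under" for r in diff)
    n_unaltered = sum(r.label == "unaltered" for r in diff)
    report["differential"] = {
        "over": n_over,
        "under": n_under,
        "unaltered": n_unaltered,
        "pct_unaltered": round(100.0 * n_unaltered / len(diff), 1) if diff else None,
        "fold_bands": qt.fold_band_counts(diff),
    }
    report["replicate_pearson"] = {}
    report["dynamic_range"] = {}
    for key, profile in (("a", profile_a), ("b", profile_b)):
        if profile.replicate_matrix is not None and profile.replicate_matrix.shape[1] >= 2:
            report["replicate_pearson"][profile.cell_line] = qt.replicate_pearson(
                profile.replicate_matrix
            )
        report["dynamic_range"][profile.cell_line] = qt.dynamic_range(profile)

    diff_by_acc = {r.accession: r for r in diff}
    altered = sorted(r.accession for r in diff if r.label != "unaltered")

    # --- enrichment --------------------------------------------------------
    if config.gmt:
        terms = en.read_gmt(config.gmt)
        background = profile_a.accessions | profile_b.accessions
        report["enrichment"] = {}
        queries = {
            "specific_a": sorted(part.specific_a),
            "specific_b": sorted(part.specific_b),
            "altered": altered,
        }
        for qname, genes in queries.items():
            if not genes:
                report["enrichment"][qname] = {"n_significant": 0, "n_clusters": 0}
                continue
            results = en.enrich_query(set(genes), terms, background)
            kept = en.filter_terms(
                results, min_genes=config.min_genes, alpha=config.alpha,
                use_fdr=config.use_fdr,
            )
            en.write_enrichment_table(results, outdir / f"enrichment_{qname}.tsv")
            kept_terms = [t for t in terms if t.term_id in {r.term_id for r in kept}]
            clusters, unclustered = en.cluster_terms(
                kept_terms,
                background,
                kappa_threshold=config.kappa_threshold,
                membership=config.membership,
                p_values={r.term_id: r.p_value for r in kept},
            )
            en.write_cluster_table(clusters, unclustered, outdir / f"clusters_{qname}.tsv")
            report["enrichment"][qname] = {
                "n_tested": len(results),
                "n_significant": len(kept),
                "n_clusters": len(clusters),
                "top_terms": [r.term_id for r in kept[:5]],
            }

    # --- interactome / topology / steiner per cell line --------------------
    if config.edges:
        all_edges = ia.read_edge_table(config.edges)
        logger.info("edges: %d records read", len(all_edges))
        scored = ia.filter_by_score(all_edges, config.score_cutoff)
        logger.info("edges: %d survive score >= %.2f", len(scored), config.score_cutoff)
        sources = (
            ia.read_expression_sources(config.source_manifest)
            if config.source_manifest
            else []
        )
        report["networks"] = {}
        for profile, specific in (
            (profile_a, part.specific_a),
            (profile_b, part.specific_b),
        ):
            name = profile.cell_line
            detected = profile.accessions
            labels = _fold_labels(profile, part, diff_by_acc, specific)
            edges_cl = [
                e for e in scored if e.a in detected or e.b in detected
            ]
            if sources:
                candidates = {e.a for e in edges_cl} | {e.b for e in edges_cl}
                kept_nodes = ia.context_filter(
                    candidates, sources, min_sources=config.min_sources,
                    detected=detected,
                )
                edges_cl = [
                    e for e in edges_cl if e.a in kept_nodes and e.b in kept_nodes
                ]
            g = ia.build_network(
                labels, edges_cl, keep_interactor_edges=config.keep_interactor_edges
            )
            ia.write_network_tables(
                g, outdir / f"network_nodes_{name}.tsv", outdir / f"network_edges_{name}.tsv"
            )
            summary = ia.network_summary(g)
            logger.info(
                "%s network: %d detected with PPIs, %d nodes, %d edges",
                name, summary["n_detected_with_edges"], summary["n_nodes"],
                summary["n_edges"],
            )

            metrics = tp.compute_node_metrics(
                g, degree_cut=config.degree_cut, bc_cut=config.bc_cut
            )
            tp.write_metrics_table(metrics, outdir / f"node_metrics_{name}.tsv")
            hubs = sorted(m.node for m in metrics if m.is_hub)
            bottlenecks = sorted(m.node for m in metrics if m.is_bottleneck)

            entry = {
                "summary": summary,
                "n_hubs": len(hubs),
                "n_bottlenecks": len(bottlenecks),
                "hub_bottlenecks": sorted(set(hubs) & set(bottlenecks)),
            }

            if g.number_of_edges() == 0:
                warnings.warn(
                    f"{name}: empty network after filtering; steiner stage skipped",
                    stacklevel=2,
                )
                logger.warning("%s: 0-edge network, steiner skipped", name)
                entry["steiner"] = None
            else:
                folds = {
                    acc: (None if labels[acc] == "specific" else diff_by_acc[acc].fold)
                    for acc in detected
                    if acc in g and labels[acc] in {"specific", "over", "under", "unaltered"}
                }
                instance = st.build_instance(
                    g, folds, beta=config.beta, cost_mode=config.cost_mode
                )
                solution = st.solve_pcst(instance, solver=config.solver)
                st.write_solution_tables(
                    solution,
                    outdir / f"steiner_nodes_{name}.tsv",
                    outdir / f"steiner_edges_{name}.tsv",
                    outdir / f"steiner_report_{name}.json",
                )
                entry["steiner"] = st.terminal_report(solution)
            report["networks"][name] = entry

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
    return report
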