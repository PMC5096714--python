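"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical shape of a two-cell-line label-free
MS comparison and its surrounding databases:

* two overlapping proteomes (default sizes 735 and 789 with 496 shared, the
  published study design) with log-normal base abundances, planted signed
  fold-changes on the shared fraction and multiplicative replicate noise;
* a scored scale-free interaction table (preferential attachment, Beta
  confidence scores) with a planted star hub, a planted bridge between two
  cliques, and a planted cheap-edge subtree over high-prize terminals whose
  optimal prize-collecting Steiner solution is known by construction;
* multi-source expression gene lists with independent per-source inclusion;
* GMT annotation terms with a subset planted to oversample a query set.

Every generator writes the same file formats the pipeline reads and a
machine-readable truth manifest, so tests exercise the I/O layer too.  A
fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import AnnotationTerm, write_gmt
from .interactome import ExpressionSource, InteractionRecord
from .quantify import ProteomeProfile

__all__ = [
    "SimulationConfig",
    "generate_proteomes",
    "generate_ppi_db",
    "generate_expression_sources",
    "generate_annotations",
    "planted_bridge_graph",
    "generate_all",
]


@dataclass
class SimulationConfig:
    """Knobs for the full synthetic study; defaults emulate the real design."""

    seed: int = 0
    # proteomes: published sizes 735 / 789 with 496 shared
    n_proteins_a: int = 735
    n_proteins_b: int = 789
    overlap_fraction: float = 496 / 735  # shared / |A|
    n_replicates: int = 3
    replicate_cv: float = 0.10
    # planted (fraction-of-shared, signed fold): 68 over / 83 under at |4|
    planted_folds: tuple[tuple[float, float], ...] = (
        (68 / 496, 4.0),
        (83 / 496, -4.0),
    )
    # unaltered ratio jitter, uniform on +/- this many log2 units
    unaltered_log2_jitter: float = 0.5
    # log-normal base abundance (ln units); sigma sized for the wide emPAI
    # dynamic range typical of label-free data
    lognormal_mu: float = math.log(0.4)
    lognormal_sigma: float = 1.2
    # interactome
    ppi_extra_interactors: int = 300
    ppi_attachment: int = 2  # preferential-attachment edges per new node
    score_beta: tuple[float, float] = (4.0, 2.0)
    hub_spokes: int = 30
    clique_size: int = 10
    n_planted_terminals: int = 6
    # expression sources
    n_sources: int = 5
    source_coverage: float = 0.5
    # annotations
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 60)
    n_planted_enriched: int = 5
    planted_query_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in (0, 1)")
        if any(not 0 < frac < 1 for frac, _ in self.planted_folds):
            raise ValueError("planted fold fractions must lie in (0, 1)")
        if sum(frac for frac, _ in self.planted_folds) >= 1:
            raise ValueError("planted fold fractions must sum to < 1")
        if self.n_sources < 2:
            raise ValueError("need at least 2 expression sources")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child generator per stage (stable across stages)."""
        return np.random.default_rng([self.seed, stream])


def _replicate_matrix(
    rng: np.random.Generator, merged: dict[str, float], n_reps: int, cv: float
) -> pd.DataFrame:
    """Multiplicative log-normal replicate noise around each merged value."""
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    idx = sorted(merged)
    base = np.array([merged[a] for a in idx])
    if sigma == 0:
        mat = np.tile(base[:, None], (1, n_reps))
    else:
        noise = rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=(len(idx), n_reps))
        mat = base[:, None] * noise
    return pd.DataFrame(mat, index=idx, columns=[f"rep{i+1}" for i in range(n_reps)])


def generate_proteomes(
    config: SimulationConfig,
) -> tuple[ProteomeProfile, ProteomeProfile, pd.DataFrame]:
    """Two overlapping proteomes + a ground-truth table.

    Shared proteins carry planted signed fold-changes (positive = higher in
    A); the remaining shared fraction jitters within +/-
    ``unaltered_log2_jitter`` log2 units.  Specific proteins exist in one
    profile only.  Returns (profile_a, profile_b, truth) where truth has one
    row per protein: accession, set membership, true fold, true label.
    """
    rng = config.rng(1)
    n_shared = round(config.overlap_fraction * config.n_proteins_a)
    n_spec_a = config.n_proteins_a - n_shared
    n_spec_b = config.n_proteins_b - n_shared
    shared_ids = [f"SH{i:04d}" for i in range(n_shared)]
    spec_a_ids = [f"AX{i:04d}" for i in range(n_spec_a)]
    spec_b_ids = [f"BX{i:04d}" for i in range(n_spec_b)]

    counts = [round(frac * n_shared) for frac, _ in config.planted_folds]
    if sum(counts) > n_shared:
        raise ValueError("planted fold counts exceed the shared set")
    order = rng.permutation(n_shared)
    truth_rows = []
    records_a: dict[str, float] = {}
    records_b: dict[str, float] = {}

    pos = 0
    assignment: dict[str, float | None] = {}  # accession -> true signed fold
    for (_, fold), cnt in zip(config.planted_folds, counts):
        for j in order[pos : pos + cnt]:
            assignment[shared_ids[j]] = fold
        pos += cnt
    for j in order[pos:]:
        assignment[shared_ids[j]] = None  # unaltered

    for acc in shared_ids:
        base = rng.lognormal(config.lognormal_mu, config.lognormal_sigma)
        fold = assignment[acc]
        if fold is None:
            ratio = 2.0 ** rng.uniform(
                -config.unaltered_log2_jitter, config.unaltered_log2_jitter
            )
            true_fold = ratio if ratio >= 1 else -1.0 / ratio
            label = "unaltered"
        else:
            ratio = abs(fold) if fold > 0 else 1.0 / abs(fold)
            true_fold = fold
            label = "over" if fold > 0 else "under"
        records_a[acc] = base * math.sqrt(ratio)
        records_b[acc] = base / math.sqrt(ratio)
        truth_rows.append(
            {"accession": acc, "set": "shared", "true_fold": true_fold, "true_label": label}
        )
    for acc in spec_a_ids:
        records_a[acc] = rng.lognormal(config.lognormal_mu, config.lognormal_sigma)
        truth_rows.append(
            {"accession": acc, "set": "specific_a", "true_fold": np.nan, "true_label": "specific"}
        )
    for acc in spec_b_ids:
        records_b[acc] = rng.lognormal(config.lognormal_mu, config.lognormal_sigma)
        truth_rows.append(
            {"accession": acc, "set": "specific_b", "true_fold": np.nan, "true_label": "specific"}
        )

    mat_a = _replicate_matrix(rng, records_a, config.n_replicates, config.replicate_cv)
    mat_b = _replicate_matrix(rng, records_b, config.n_replicates, config.replicate_cv)
    # merged profile = mean over replicates (all detected here: no dropout)
    profile_a = ProteomeProfile(
        "A", {a: float(v) for a, v in mat_a.mean(axis=1).items()}, mat_a
    )
    profile_b = ProteomeProfile(
        "B", {a: float(v) for a, v in mat_b.mean(axis=1).items()}, mat_b
    )
    truth = pd.DataFrame(truth_rows).sort_values("accession").reset_index(drop=True)
    return profile_a, profile_b, truth


def planted_bridge_graph(clique_size: int = 10) -> tuple[nx.Graph, str]:
    """Two cliques joined through a single bridge node linked to every
    clique member; the bridge carries the highest betweenness by
    construction.  Returns (graph, bridge_node_id)."""
    g = nx.Graph()
    bridge = "BRIDGE"
    for prefix in ("CLQA", "CLQB"):
        members = [f"{prefix}{i:02d}" for i in range(clique_size)]
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                g.add_edge(u, v)
            g.add_edge(bridge, u)
    return g, bridge


def generate_ppi_db(
    config: SimulationConfig, detected: Sequence[str]
) -> tuple[list[InteractionRecord], dict]:
    """Scored scale-free interaction table + planted-structure manifest.

    The backbone is a preferential-attachment graph over the detected
    proteins plus ``ppi_extra_interactors`` undetected partners, with Beta
    confidence scores.  Planted extras, recorded in the manifest:

    * a star hub (fresh node, exactly ``hub_spokes`` edges);
    * a bridge node joining two cliques (a separate component — highest
      betweenness there by construction);
    * a cheap-edge subtree over ``n_planted_terminals`` fresh high-prize
      terminals through one connector node, plus expensive decoy edges; the
      subtree is the optimal prize-collecting Steiner solution of its
      component.
    """
    rng = config.rng(2)
    detected = [str(d) for d in detected]
    interactors = [f"IX{i:04d}" for i in range(config.ppi_extra_interactors)]
    universe = detected + interactors
    backbone = nx.barabasi_albert_graph(
        len(universe), config.ppi_attachment, seed=int(rng.integers(2**31))
    )
    relabel = dict(enumerate(universe))
    a_, b_ = config.score_beta
    records = [
        InteractionRecord(relabel[u], relabel[v], float(rng.beta(a_, b_)))
        for u, v in backbone.edges
    ]

    # planted star hub
    hub = "PLANTEDHUB"
    spoke_targets = rng.choice(universe, size=config.hub_spokes, replace=False)
    for t in spoke_targets:
        records.append(InteractionRecord(hub, str(t), 0.95))

    # planted bridge component
    bridge_graph, bridge = planted_bridge_graph(config.clique_size)
    for u, v in bridge_graph.edges:
        records.append(InteractionRecord(u, v, 0.9))

    # planted PCST component: terminals on a cheap star through a connector,
    # decoy terminal-terminal edges too expensive to prefer
    terminals = [f"TM{i:02d}" for i in range(config.n_planted_terminals)]
    connector = "STNR00"
    tree_edges = [(connector, t) for t in terminals]
    for u, v in tree_edges:
        records.append(InteractionRecord(u, v, 0.99))
    for i in range(len(terminals) - 1):
        records.append(InteractionRecord(terminals[i], terminals[i + 1], 0.2))

    manifest = {
        "hub": hub,
        "hub_spokes": int(config.hub_spokes),
        "bridge": bridge,
        "bridge_component": sorted(bridge_graph.nodes),
        "pcst_terminals": terminals,
        "pcst_connector": connector,
        "pcst_tree_edges": [sorted(e) for e in tree_edges],
        "pcst_terminal_prize": 5.0,
        "backbone_top_degree": sorted(
            (relabel[n] for n, _ in sorted(
                backbone.degree, key=lambda nd: (-nd[1], nd[0])
            )[:10])
        ),
    }
    return records, manifest


def generate_expression_sources(
    config: SimulationConfig, genes: Sequence[str]
) -> tuple[list[ExpressionSource], set[str]]:
    """Independent Bernoulli(source_coverage) inclusion per gene per source.

    Returns the sources and the truth set of genes present in >= 2 sources.
    """
    rng = config.rng(3)
    genes = [str(g) for g in genes]
    membership = rng.random((len(genes), config.n_sources)) < config.source_coverage
    sources = []
    for s in range(config.n_sources):
        included = frozenset(g for g, m in zip(genes, membership[:, s]) if m)
        if not included:  # degenerate at coverage ~ 0; keep the source valid
            included = frozenset({genes[int(rng.integers(len(genes)))]})
        sources.append(ExpressionSource(f"source_{s+1}", included))
    truth = {g for g, row in zip(genes, membership) if row.sum() >= 2}
    return sources, truth


def generate_annotations(
    config: SimulationConfig, background: Sequence[str], query: Sequence[str]
) -> tuple[list[AnnotationTerm], set[str]]:
    """GMT-style terms over the background; a planted subset oversamples the
    query (``planted_query_fraction`` of their genes drawn from it).

    Returns (terms, planted_term_ids).
    """
    rng = config.rng(4)
    background = sorted(str(g) for g in set(background))
    query = sorted(str(g) for g in set(query))
    if not set(query) <= set(background):
        raise ValueError("query must be a subset of the background")
    non_query = sorted(set(background) - set(query))
    lo, hi = config.term_size_range
    categories = ("CC", "BP", "MF")
    terms = []
    planted: set[str] = set()
    for i in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        term_id = f"T{i:04d}"
        if i < config.n_planted_enriched:
            n_from_query = min(len(query), max(1, round(config.planted_query_fraction * size)))
            picked = list(rng.choice(query, size=n_from_query, replace=False))
            n_rest = min(len(non_query), size - n_from_query)
            if n_rest > 0:
                picked += list(rng.choice(non_query, size=n_rest, replace=False))
            planted.add(term_id)
        else:
            picked = list(rng.choice(background, size=min(size, len(background)), replace=False))
        terms.append(
            AnnotationTerm(
                term_id,
                f"synthetic term {i}",
                categories[i % len(categories)],
                frozenset(picked),
            )
        )
    return terms, planted


def generate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a full synthetic dataset directory + truth manifest.

    Files: quant_a.tsv, quant_b.tsv, edges.tsv, sources/source_*.txt,
    sources/manifest.json, annotations.gmt, truth.json.  Returns the truth
    manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile_a, profile_b, truth_proteome = generate_proteomes(config)

    for profile, fname in ((profile_a, "quant_a.tsv"), (profile_b, "quant_b.tsv")):
        rows = []
        mat = profile.replicate_matrix
        for acc in mat.index:
            for rep in mat.columns:
                e = float(mat.loc[acc, rep])
                # counts are a consistent integer stand-in; the written empai
                # column is authoritative and read back as-is
                n_observable = 30
                n_observed = max(1, round(n_observable * math.log10(e + 1.0))) if e > 0 else 0
                rows.append(
                    {
                        "accession": acc,
                        "gene_symbol": acc,
                        "replicate_id": rep,
                        "n_observed": n_observed,
                        "n_observable": n_observable,
                        "empai": e,
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / fname, sep="\t", index=False)

    detected = sorted(set(profile_a.records) | set(profile_b.records))
    edges, ppi_manifest = generate_ppi_db(config, detected)
    pd.DataFrame(
        [{"a": e.a, "b": e.b, "score": round(e.score, 6)} for e in edges]
    ).to_csv(outdir / "edges.tsv", sep="\t", index=False)

    interactor_universe = sorted({e.a for e in edges} | {e.b for e in edges})
    sources, context_truth = generate_expression_sources(config, interactor_universe)
    srcdir = outdir / "sources"
    srcdir.mkdir(exist_ok=True)
    manifest_paths = {}
    for s in sources:
        p = srcdir / f"{s.source_name}.txt"
        p.write_text("\n".join(sorted(s.genes)) + "\n")
        manifest_paths[s.source_name] = p.name
    (srcdir / "manifest.json").write_text(json.dumps(manifest_paths, indent=2) + "\n")

    shared = sorted(set(profile_a.records) & set(profile_b.records))
    query = sorted(
        truth_proteome.loc[truth_proteome["true_label"].isin(["over", "under"]), "accession"]
    )
    terms, planted_terms = generate_annotations(config, detected, query)
    write_gmt(terms, outdir / "annotations.gmt")

    truth = {
        "config": asdict(config),
        "venn": {
            "total_a": len(profile_a),
            "total_b": len(profile_b),
            "shared": len(shared),
            "specific_a": len(profile_a) - len(shared),
            "specific_b": len(profile_b) - len(shared),
        },
        "differential": {
            "over": int((truth_proteome["true_label"] == "over").sum()),
            "under": int((truth_proteome["true_label"] == "under").sum()),
            "unaltered": int((truth_proteome["true_label"] == "unaltered").sum()),
        },
        "ppi": ppi_manifest,
        "context_positive": sorted(context_truth),
        "planted_terms": sorted(planted_terms),
        "enrichment_query": query,
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, default=float) + "\n")
    truth_proteome.to_csv(outdir / "proteome_truth.tsv", sep="\t", index=False)
    return truth
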