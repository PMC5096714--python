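"""Scored interaction loading, confidence/context filtering, network assembly.

Interactions come as scored undirected pairs (HIPPIE-style confidence in
[0, 1]).  Two filters precede assembly: a confidence cutoff (inclusive;
0.63 = medium, 0.73 = high confidence in the HIPPIE convention) and a
tissue-context consensus filter keeping candidate interactors attested as
expressed by at least ``min_sources`` independent expression sources.
MS-detected proteins bypass the context filter — their detection is itself
evidence of expression.  The assembled first-neighbour network keeps edges
with at least one detected endpoint, drops self-loops, and collapses
duplicate pairs to the highest score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .quantify import normalize_symbol

__all__ = [
    "InteractionRecord",
    "ExpressionSource",
    "filter_by_score",
    "context_filter",
    "build_network",
    "network_summary",
    "read_edge_table",
    "read_expression_sources",
    "write_network_tables",
]


@dataclass(frozen=True)
class InteractionRecord:
    """Undirected scored interaction; (a, b) is stored sorted so the pair
    identity is orientation-free."""

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        na, nb = sorted((normalize_symbol(self.a), normalize_symbol(self.b)))
        object.__setattr__(self, "a", na)
        object.__setattr__(self, "b", nb)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


@dataclass(frozen=True)
class ExpressionSource:
    """One tissue/cell-line expression evidence source (a gene list)."""

    source_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"expression source {self.source_name!r} is empty")


def filter_by_score(
    edges: Iterable[InteractionRecord], cutoff: float
) -> list[InteractionRecord]:
    """Keep edges with confidence score >= cutoff (inclusive)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    return [e for e in edges if e.score >= cutoff]


def context_filter(
    candidates: set[str],
    sources: Sequence[ExpressionSource],
    min_sources: int = 2,
    detected: set[str] | None = None,
) -> set[str]:
    """Consensus expression filter on candidate interactors.

    A candidate survives if it appears in at least ``min_sources`` distinct
    sources.  Symbols in ``detected`` (the MS lists) bypass the filter.
    """
    if min_sources > len(sources):
        raise ValueError(
            f"min_sources={min_sources} exceeds the {len(sources)} sources provided"
        )
    detected = detected or set()
    kept = set()
    for gene in candidates:
        if gene in detected:
            kept.add(gene)
            continue
        hits = sum(gene in s.genes for s in sources)
        if hits >= min_sources:
            kept.add(gene)
    return kept


def build_network(
    detected: Mapping[str, str] | set[str],
    edges: Iterable[InteractionRecord],
    keep_interactor_edges: bool = False,
) -> nx.Graph:
    """Assemble the first-neighbour network around detected proteins.

    ``detected`` maps symbol -> fold label (over/under/unaltered/specific);
    a plain set gets label ``none``.  Edges must already be score- and
    context-filtered.  Self-loops are dropped; duplicate pairs collapse to
    the max score.  By default only edges with >= 1 detected endpoint are
    retained; ``keep_interactor_edges`` also keeps interactor-interactor
    edges among nodes already brought in by a detected neighbour.

    Node attributes: ``origin`` ("detected" | "interactor"), ``fold_label``.
    Edge attribute: ``score``.
    """
    if isinstance(detected, Mapping):
        labels = {normalize_symbol(s): lab for s, lab in detected.items()}
    else:
        labels = {normalize_symbol(s): "none" for s in detected}

    best: dict[tuple[str, str], float] = {}
    for e in edges:
        if e.a == e.b:
            continue
        if (e.pair not in best) or (e.score > best[e.pair]):
            best[e.pair] = e.score

    g = nx.Graph()
    g.add_nodes_from(labels)
    primary = [(p, s) for p, s in best.items() if p[0] in labels or p[1] in labels]
    for (a, b), score in primary:
        g.add_edge(a, b, score=score)
    if keep_interactor_edges:
        nodes = set(g.nodes)
        for (a, b), score in best.items():
            if a in nodes and b in nodes and not g.has_edge(a, b):
                g.add_edge(a, b, score=score)

    for node in g.nodes:
        g.nodes[node]["origin"] = "detected" if node in labels else "interactor"
        g.nodes[node]["fold_label"] = labels.get(node, "none")
    return g


def network_summary(g: nx.Graph) -> dict[str, int]:
    """Survivor counts in the style a network build log reports them."""
    detected = [n for n, d in g.nodes(data=True) if d.get("origin") == "detected"]
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_detected": len(detected),
        "n_detected_with_edges": sum(g.degree(n) > 0 for n in detected),
        "n_interactors": g.number_of_nodes() - len(detected),
    }


# ---------------------------------------------------------------------------
# I/O

def read_edge_table(path: str | Path) -> list[InteractionRecord]:
    """Read a scored edge list.

    Two dialects are sniffed per line: 3-column TSV ``a<TAB>b<TAB>score`` and
    SIF-with-score ``a<TAB>pp<TAB>b<TAB>score``.
    """
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            if len(fields) == 3:
                a, b, score = fields
            elif len(fields) == 4 and fields[1] == "pp":
                a, _, b, score = fields
            else:
                raise ValueError("expected 3 columns or SIF 'a pp b score'")
            records.append(InteractionRecord(a, b, float(score)))
        except ValueError as exc:
            if ln == 1:  # tolerate a header row
                continue
            raise ValueError(f"{path}:{ln}: {exc}") from exc
    return records


def read_expression_sources(manifest_path: str | Path) -> list[ExpressionSource]:
    """Load expression sources from a manifest JSON {source_name: path};
    each source file lists one gene per line.  Relative paths resolve
    against the manifest's directory."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    sources = []
    for name, rel in sorted(manifest.items()):
        p = Path(rel)
        if not p.is_absolute():
            p = manifest_path.parent / p
        genes = frozenset(
            normalize_symbol(g) for g in p.read_text().splitlines() if g.strip()
        )
        sources.append(ExpressionSource(name, genes))
    return sources


def write_network_tables(
    g: nx.Graph, node_path: str | Path, edge_path: str | Path
) -> None:
    """Cytoscape-loadable node attribute and edge tables."""
    pd.DataFrame(
        [
            {
                "node": n,
                "origin": d.get("origin", ""),
                "fold_label": d.get("fold_label", ""),
            }
            for n, d in sorted(g.nodes(data=True))
        ]
    ).to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {"a": a, "b": b, "score": d.get("score", float("nan"))}
            for a, b, d in sorted(g.edges(data=True))
        ]
    ).to_csv(edge_path, sep="\t", index=False)
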