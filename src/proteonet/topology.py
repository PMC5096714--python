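"""Degree / betweenness centrality and hub-bottleneck classification.

Hubs are nodes whose degree reaches a cutoff (default 10, inclusive);
bottlenecks are nodes whose normalized betweenness centrality strictly
exceeds a cutoff (default 0.3).  Betweenness is Brandes' exact algorithm on
the unweighted graph with fractional credit over equal-length shortest
paths, normalized by (n-1)(n-2)/2 where n is the node's connected-component
size — the NetworkAnalyzer convention, which keeps values in [0, 1] per
component.  Edge confidence scores can optionally define weighted shortest
paths, but the unweighted convention is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "NodeMetrics",
    "degree",
    "betweenness",
    "classify_hub_bottleneck",
    "compute_node_metrics",
    "write_metrics_table",
]


@dataclass(frozen=True)
class NodeMetrics:
    node: str
    degree: int
    betweenness: float
    is_hub: bool
    is_bottleneck: bool


def degree(g: nx.Graph) -> dict[str, int]:
    """Edge count per node (the graph must be self-loop-free)."""
    if any(a == b for a, b in nx.selfloop_edges(g)):
        raise ValueError("graph contains self-loops")
    return dict(g.degree())


def betweenness(g: nx.Graph, weighted: bool = False) -> dict[str, float]:
    """Exact normalized betweenness centrality, per connected component.

    Each component is treated independently: shortest paths never cross
    components and the [0, 1] normalization uses the component's own size.
    Components with fewer than 3 nodes contribute zeros.  With
    ``weighted=True`` shortest paths minimize ``-log`` is not applied — the
    raw ``score`` edge attribute is used as a distance; the default ignores
    weights entirely.
    """
    result: dict[str, float] = {}
    weight = "score" if weighted else None
    for comp in nx.connected_components(g):
        if len(comp) < 3:
            result.update({v: 0.0 for v in comp})
            continue
        sub = g.subgraph(comp)
        result.update(nx.betweenness_centrality(sub, normalized=True, weight=weight))
    return result


def classify_hub_bottleneck(
    degrees: Mapping[str, int],
    betweennesses: Mapping[str, float],
    degree_cut: int = 10,
    bc_cut: float = 0.3,
) -> list[NodeMetrics]:
    """Flag hubs (degree >= degree_cut, inclusive) and bottlenecks
    (betweenness > bc_cut, strict), sorted by node id.

    The hub cutoff is inclusive: published hub tables flag degree-10 nodes
    as hubs at a nominal cutoff of 10.  The bottleneck cutoff stays strict.
    """
    if set(degrees) != set(betweennesses):
        raise ValueError("degree and betweenness maps cover different nodes")
    return [
        NodeMetrics(
            node=v,
            degree=int(degrees[v]),
            betweenness=float(betweennesses[v]),
            is_hub=degrees[v] >= degree_cut,
            is_bottleneck=betweennesses[v] > bc_cut,
        )
        for v in sorted(degrees)
    ]


def compute_node_metrics(
    g: nx.Graph,
    degree_cut: int = 10,
    bc_cut: float = 0.3,
    weighted: bool = False,
) -> list[NodeMetrics]:
    """Degree + betweenness + hub/bottleneck flags for every node."""
    return classify_hub_bottleneck(
        degree(g), betweenness(g, weighted=weighted), degree_cut, bc_cut
    )


def write_metrics_table(metrics: Sequence[NodeMetrics], path: str | Path) -> None:
    """Cytoscape-importable node metrics TSV."""
    pd.DataFrame(
        [
            {
                "node": m.node,
                "degree": m.degree,
                "betweenness": m.betweenness,
                "is_hub": m.is_hub,
                "is_bottleneck": m.is_bottleneck,
            }
            for m in metrics
        ]
    ).to_csv(path, sep="\t", index=False)
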