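"""Prize-collecting Steiner tree (PCST) integration of proteome and network.

Detected proteins become prized terminals — prize proportional to the
magnitude of their expression change, with a floor so that every detected
protein carries weight — and interaction confidence becomes edge cost.  The
solver returns a single tree minimizing

    sum of prizes of excluded terminals  +  sum of costs of tree edges

(the Goemans-Williamson unrooted PCST objective).  Terminals the tree cannot
profitably reach are excluded and pay their prize as penalty; interactors
(prize 0) may be pulled in as Steiner nodes to connect terminals cheaply.

Two solvers are provided.  The exact solver enumerates connected node
subsets and takes the minimum spanning tree over each — optimal, feasible up
to roughly a dozen nodes.  The heuristic builds candidate trees (metric-
closure Steiner approximation over each component's terminals, plus the
component MST) and strong-prunes each: a rooted dynamic program that keeps a
subtree branch only when its collected prize exceeds the cost of attaching
it, which is optimal for a fixed tree.  The heuristic is therefore never
worse than excluding every terminal, and returns exact optima on most small
instances.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import networkx as nx
from networkx.algorithms import approximation as nx_approx

__all__ = [
    "PCSTInstance",
    "PCSTSolution",
    "build_instance",
    "solve_pcst",
    "terminal_report",
    "write_solution_tables",
]

EPS = 1e-6
EXACT_NODE_LIMIT = 12

Edge = tuple[str, str]


def _edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class PCSTInstance:
    """Graph + node prizes + edge costs; terminals are the prized nodes."""

    graph: nx.Graph
    prize: dict[str, float]
    cost: dict[Edge, float]
    beta: float = 1.0

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.prize.values()):
            raise ValueError("prizes must be non-negative")
        if any(c <= 0 for c in self.cost.values()):
            raise ValueError("edge costs must be positive")

    @property
    def terminals(self) -> set[str]:
        return {v for v, p in self.prize.items() if p > 0}

    def edge_cost(self, a: str, b: str) -> float:
        return self.cost[_edge(a, b)]


@dataclass(frozen=True)
class PCSTSolution:
    nodes: frozenset[str]
    edges: frozenset[Edge]
    included_terminals: frozenset[str]
    excluded_terminals: frozenset[str]
    objective: float


def build_instance(
    network: nx.Graph,
    fold_by_protein: Mapping[str, float | None],
    beta: float = 1.0,
    cost_mode: Literal["log", "linear"] = "log",
    specific_prize: float = 2.0,
) -> PCSTInstance:
    """Turn an assembled network plus fold-changes into a PCST instance.

    ``fold_by_protein`` maps each detected protein to its signed fold, or to
    ``None`` for cell-line-specific proteins (no finite fold).  Prizes:

    * detected with fold f:  ``beta * max(1, |log2 |f||)`` — the floor keeps
      unaltered detected proteins as genuine terminals;
    * detected specific:     ``beta * specific_prize``;
    * interactors:           0 (candidate Steiner nodes).

    Costs: ``-ln(score)`` (log mode, default) or ``1 - score + eps``
    (linear), both floored at ``eps`` so perfect-confidence edges stay
    positive.  A zero-score edge has infinite log cost and is rejected.
    """
    prize: dict[str, float] = {}
    for v in network.nodes:
        if v in fold_by_protein:
            f = fold_by_protein[v]
            if f is None:
                prize[v] = beta * specific_prize
            else:
                prize[v] = beta * max(1.0, abs(math.log2(abs(f))))
        else:
            prize[v] = 0.0

    cost: dict[Edge, float] = {}
    for a, b, data in network.edges(data=True):
        score = data.get("score", 1.0)
        if score <= 0:
            raise ValueError(f"edge ({a}, {b}) has score {score}: infinite cost")
        if cost_mode == "log":
            c = max(-math.log(score), EPS)
        elif cost_mode == "linear":
            c = (1.0 - score) + EPS
        else:
            raise ValueError(f"unknown cost mode: {cost_mode!r}")
        cost[_edge(a, b)] = c
    return PCSTInstance(graph=network, prize=prize, cost=cost, beta=beta)


def _objective(instance: PCSTInstance, nodes: set[str], edges: set[Edge]) -> float:
    excluded = sum(p for v, p in instance.prize.items() if p > 0 and v not in nodes)
    return excluded + sum(instance.cost[e] for e in edges)


def _solution(instance: PCSTInstance, nodes: set[str], edges: set[Edge]) -> PCSTSolution:
    terms = instance.terminals
    return PCSTSolution(
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        included_terminals=frozenset(terms & nodes),
        excluded_terminals=frozenset(terms - nodes),
        objective=_objective(instance, nodes, edges),
    )


def _cost_graph(instance: PCSTInstance) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(instance.graph.nodes)
    for (a, b), c in instance.cost.items():
        g.add_edge(a, b, cost=c)
    return g


def _solve_exact(instance: PCSTInstance) -> PCSTSolution:
    """Optimal PCST by enumeration of connected node subsets + MST.

    For a fixed node set the cheapest spanning tree is the MST of the
    induced subgraph, so enumerating connected subsets is exhaustive over
    trees.  Deterministic tie-break: lexicographically smallest sorted node
    tuple among optima.
    """
    g = _cost_graph(instance)
    nodes = sorted(g.nodes)
    if len(nodes) > 2 * EXACT_NODE_LIMIT:
        raise ValueError(
            f"exact solver limited to {2 * EXACT_NODE_LIMIT} nodes, got {len(nodes)}"
        )
    best: tuple[float, tuple[str, ...], set[str], set[Edge]] | None = None
    for r in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            sub = g.subgraph(combo)
            if not nx.is_connected(sub):
                continue
            mst_edges = {
                _edge(a, b) for a, b, _ in nx.minimum_spanning_edges(sub, weight="cost")
            }
            obj = _objective(instance, set(combo), mst_edges)
            key = (obj, combo)
            if best is None or key < (best[0], best[1]):
                best = (obj, combo, set(combo), mst_edges)
    assert best is not None  # len(nodes) >= 1 via terminal check upstream
    return _solution(instance, best[2], best[3])


def _strong_prune(
    tree: nx.Graph, instance: PCSTInstance
) -> tuple[set[str], set[Edge], float]:
    """Optimal subtree of a fixed tree: maximize collected prize - cost.

    Rooted DP, evaluated from every root; net(v) = prize(v) + sum over
    children of max(0, net(child) - cost(edge)).  Returns the node set,
    edge set, and net value of the best subtree (possibly a single node).
    """
    prize = instance.prize
    best_net = -math.inf
    best_nodes: set[str] = set()
    best_edges: set[Edge] = set()
    for root in sorted(tree.nodes):
        net: dict[str, float] = {}
        keep: dict[str, list[str]] = {}
        order = list(nx.dfs_postorder_nodes(tree, root))
        parent = {
            c: p for p, c in nx.bfs_edges(tree, root)
        }
        for v in order:
            net_v = prize.get(v, 0.0)
            keep[v] = []
            for c in tree.neighbors(v):
                if parent.get(c) != v:
                    continue
                gain = net[c] - instance.edge_cost(v, c)
                if gain > 0:
                    net_v += gain
                    keep[v].append(c)
            net[v] = net_v
        if net[root] > best_net + 1e-12:
            nodes = {root}
            edges: set[Edge] = set()
            stack = [root]
            while stack:
                v = stack.pop()
                for c in keep[v]:
                    nodes.add(c)
                    edges.add(_edge(v, c))
                    stack.append(c)
            best_net, best_nodes, best_edges = net[root], nodes, edges
    return best_nodes, best_edges, best_net


MAX_PRIZE_THRESHOLDS = 8


def _solve_heuristic(instance: PCSTInstance) -> PCSTSolution:
    g = _cost_graph(instance)
    terminals = instance.terminals
    candidates: list[tuple[set[str], set[Edge]]] = []
    # single best terminal is always a feasible tree (objective < all-excluded)
    top = max(sorted(terminals), key=lambda t: instance.prize[t])
    candidates.append(({top}, set()))
    for comp in nx.connected_components(g):
        comp_terms = sorted(terminals & comp)
        if not comp_terms:
            continue
        sub = g.subgraph(comp)
        trees = []
        if len(comp) >= 2:
            trees.append(nx.minimum_spanning_tree(sub, weight="cost"))
        # sweep prize thresholds: low-prize terminals may not be worth
        # routing to, and dropping them changes the approximate tree shape
        prizes = sorted({instance.prize[t] for t in comp_terms}, reverse=True)
        if len(prizes) > MAX_PRIZE_THRESHOLDS:
            idx = [round(i * (len(prizes) - 1) / (MAX_PRIZE_THRESHOLDS - 1))
                   for i in range(MAX_PRIZE_THRESHOLDS)]
            prizes = [prizes[i] for i in idx]
        for theta in prizes:
            subset = [t for t in comp_terms if instance.prize[t] >= theta]
            if len(subset) >= 2:
                trees.append(nx_approx.steiner_tree(sub, subset, weight="cost"))
        for t in trees:
            if t.number_of_nodes() == 0:
                continue
            nodes, edges, _ = _strong_prune(t, instance)
            candidates.append((nodes, edges))
    best = min(
        candidates,
        key=lambda ne: (_objective(instance, ne[0], ne[1]), tuple(sorted(ne[0]))),
    )
    return _solution(instance, best[0], best[1])


def solve_pcst(
    instance: PCSTInstance,
    solver: Literal["exact", "heuristic", "auto"] = "auto",
    exact_limit: int = EXACT_NODE_LIMIT,
) -> PCSTSolution:
    """Solve a PCST instance; ``auto`` picks exact up to ``exact_limit`` nodes."""
    if not instance.terminals:
        raise ValueError("instance has no terminals (no positive prize)")
    if solver == "auto":
        solver = "exact" if instance.graph.number_of_nodes() <= exact_limit else "heuristic"
    if solver == "exact":
        return _solve_exact(instance)
    if solver == "heuristic":
        return _solve_heuristic(instance)
    raise ValueError(f"unknown solver: {solver!r}")


def terminal_report(solution: PCSTSolution) -> dict[str, float]:
    """Included/excluded terminal counts and percentages (1 decimal)."""
    n_inc = len(solution.included_terminals)
    n_exc = len(solution.excluded_terminals)
    total = n_inc + n_exc
    if total == 0:
        raise ValueError("solution has no terminals")
    return {
        "n_terminals": total,
        "included": n_inc,
        "excluded": n_exc,
        "pct_included": round(100.0 * n_inc / total, 1),
        "pct_excluded": round(100.0 * n_exc / total, 1),
        "objective": solution.objective,
    }


def write_solution_tables(
    solution: PCSTSolution,
    node_path: str | Path,
    edge_path: str | Path,
    report_path: str | Path | None = None,
) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "node": n,
                "terminal": n in solution.included_terminals,
            }
            for n in sorted(solution.nodes)
        ]
    ).to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(
        [{"a": a, "b": b} for a, b in sorted(solution.edges)]
    ).to_csv(edge_path, sep="\t", index=False)
    if report_path is not None:
        Path(report_path).write_text(
            json.dumps(terminal_report(solution), indent=2) + "\n"
        )
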