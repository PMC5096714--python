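"""Independent brute-force oracles used across the test suite.

Each oracle deliberately takes a different algorithmic route from the
implementation it checks: betweenness by explicit shortest-path
enumeration, PCST by exhaustive search over edge subsets, the
hypergeometric tail by exact rational arithmetic, set partitioning by a
double loop.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx


def betweenness_oracle(g: nx.Graph) -> dict:
    """Normalized betweenness by enumerating every shortest path.

    BFS from each source gives distances and predecessor DAGs; all shortest
    paths are expanded explicitly and each interior node credited
    1/(number of shortest paths) per unordered pair.  Normalization is per
    connected component: (n-1)(n-2)/2 with n the component size.
    """
    score = {v: 0.0 for v in g.nodes}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        n = len(nodes)
        if n < 3:
            continue
        norm = (n - 1) * (n - 2) / 2
        for s, t in itertools.combinations(nodes, 2):
            paths = list(nx.all_shortest_paths(g, s, t))
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
        for v in nodes:
            score[v] /= norm
    return score


def pcst_oracle(g: nx.Graph, prize: dict, cost: dict) -> float:
    """Optimal PCST objective by exhaustive search over edge subsets.

    Every subset of edges that forms a tree (plus every single-node tree)
    is scored as excluded-prize + edge-cost.  Exponential; only for tiny
    graphs.
    """
    total_prize = sum(p for p in prize.values() if p > 0)
    edges = list(g.edges)

    def objective(nodes: set, used_edges: list) -> float:
        collected = sum(prize[v] for v in nodes if prize[v] > 0)
        return total_prize - collected + sum(
            cost[tuple(sorted(e))] for e in used_edges
        )

    best = min(objective({v}, []) for v in g.nodes)
    for r in range(1, len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            sub = nx.Graph(subset)
            if sub.number_of_edges() == sub.number_of_nodes() - 1 and nx.is_connected(sub):
                best = min(best, objective(set(sub.nodes), list(subset)))
    return best


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), rational arithmetic."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(max(k, 0), min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return total


def partition_oracle(set_a, set_b):
    """Venn decomposition by a double membership loop."""
    shared = {x for x in set_a if x in set_b}
    only_a = {x for x in set_a if x not in set_b}
    only_b = {x for x in set_b if x not in set_a}
    return shared, only_a, only_b
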