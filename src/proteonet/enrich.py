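"""Term enrichment and functional-annotation clustering.

Enrichment of a query protein set against GMT-style annotation terms uses the
right-sided hypergeometric test (exact tail, no normal approximation) with
Benjamini-Hochberg FDR control, followed by DAVID-style filtering (minimum
gene hits plus a significance cutoff) and kappa-score term clustering: terms
whose gene memberships agree beyond chance (Cohen's kappa over a common
background) are grouped, seed groups sharing more than half their members are
merged, and each cluster is represented by its lowest-p term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTerm",
    "EnrichmentResult",
    "TermCluster",
    "hypergeom_enrichment",
    "bh_fdr",
    "enrich_query",
    "filter_terms",
    "kappa_similarity",
    "cluster_terms",
    "read_gmt",
    "write_gmt",
    "write_enrichment_table",
    "write_cluster_table",
]

Category = Literal["CC", "BP", "MF"]


@dataclass(frozen=True)
class AnnotationTerm:
    """A named gene set (GO-style term)."""

    term_id: str
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id} has no genes")


@dataclass(frozen=True)
class EnrichmentResult:
    """Right-tail hypergeometric outcome for one term against one query.

    k = query hits in the term, K = term size in the background, n = query
    size, N = background size.
    """

    term_id: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float = float("nan")


@dataclass(frozen=True)
class TermCluster:
    members: tuple[str, ...]
    representative: str


def hypergeom_enrichment(
    query: set[str], term: AnnotationTerm, background: set[str]
) -> EnrichmentResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); exact right tail.

    The query must be a subset of the background; term genes are intersected
    with the background before testing.
    """
    if not query:
        raise ValueError("empty query set")
    if not background:
        raise ValueError("empty background set")
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query is not a subset of the background (e.g. {extra})")
    term_genes = term.genes & background
    N, K, n = len(background), len(term_genes), len(query)
    k = len(query & term_genes)
    # sf(k-1) is the exact upper tail P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(term.term_id, k=k, K=K, n=n, N=N, p_value=min(p, 1.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_query(
    query: set[str],
    terms: Sequence[AnnotationTerm],
    background: set[str],
) -> list[EnrichmentResult]:
    """Test every term against one query and attach BH-adjusted values.

    Terms with no gene in the background are skipped with a warning.
    Results come back sorted by (p_value, term_id).
    """
    raw = []
    for term in terms:
        if not term.genes & background:
            warnings.warn(
                f"term {term.term_id} has no genes in the background; skipped",
                stacklevel=2,
            )
            continue
        raw.append(hypergeom_enrichment(query, term, background))
    if not raw:
        return []
    fdrs = bh_fdr([r.p_value for r in raw])
    adjusted = [
        EnrichmentResult(r.term_id, r.k, r.K, r.n, r.N, r.p_value, fdr=float(q))
        for r, q in zip(raw, fdrs)
    ]
    return sorted(adjusted, key=lambda r: (r.p_value, r.term_id))


def filter_terms(
    results: Iterable[EnrichmentResult],
    min_genes: int = 3,
    alpha: float = 0.05,
    use_fdr: bool = False,
) -> list[EnrichmentResult]:
    """Keep terms with at least ``min_genes`` query hits and a significant
    statistic: raw p <= alpha by default, or BH FDR < alpha in FDR mode."""
    kept = []
    for r in results:
        if r.k < min_genes:
            continue
        if use_fdr:
            if r.fdr < alpha:
                kept.append(r)
        elif r.p_value <= alpha:
            kept.append(r)
    return kept


def kappa_similarity(
    genes_a: set[str], genes_b: set[str], background: set[str]
) -> float:
    """Cohen's kappa on the 2x2 gene-membership agreement table.

    Each background gene is scored as in/out of each set; kappa is the
    chance-corrected agreement of the two membership vectors.  When expected
    agreement is 1 (both sets empty or both equal to the background) kappa is
    undefined; it is defined here as 1 for identical sets, else 0, with a
    warning.
    """
    if not genes_a <= background or not genes_b <= background:
        raise ValueError("term gene sets must be subsets of the background")
    N = len(background)
    if N == 0:
        raise ValueError("empty background")
    a = len(genes_a & genes_b)              # in both
    b = len(genes_a - genes_b)              # A only
    c = len(genes_b - genes_a)              # B only
    d = N - a - b - c                       # in neither
    observed = (a + d) / N
    expected = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if expected == 1.0:
        warnings.warn("degenerate kappa (expected agreement = 1)", stacklevel=2)
        return 1.0 if genes_a == genes_b else 0.0
    return (observed - expected) / (1.0 - expected)


def cluster_terms(
    terms: Sequence[AnnotationTerm],
    background: set[str],
    kappa_threshold: float = 0.35,
    membership: int = 2,
    p_values: dict[str, float] | None = None,
) -> tuple[list[TermCluster], list[str]]:
    """DAVID-style functional annotation clustering.

    Seed groups are formed from each term plus its kappa-neighbours (kappa >=
    threshold) and retained when they reach the ``membership`` size; groups
    are then merged iteratively whenever they share more than 50% of the
    smaller group's members.  Ties and iteration order are fixed by
    lexicographic term_id, so the output is deterministic.

    Returns ``(clusters, unclustered_term_ids)``.  Each cluster's
    representative is its lowest-p member when ``p_values`` is given, else
    the lexicographically first member.
    """
    ids = sorted(t.term_id for t in terms)
    by_id = {t.term_id: t for t in terms}
    if len(ids) != len(terms):
        raise ValueError("duplicate term_ids")

    kappa = {}
    for i, ti in enumerate(ids):
        for tj in ids[i + 1 :]:
            kappa[(ti, tj)] = kappa_similarity(
                set(by_id[ti].genes) & background,
                set(by_id[tj].genes) & background,
                background,
            )

    def pair_kappa(x: str, y: str) -> float:
        return kappa[(x, y) if (x, y) in kappa else (y, x)]

    seeds = []
    for tid in ids:
        group = {tid} | {o for o in ids if o != tid and pair_kappa(tid, o) >= kappa_threshold}
        if len(group) >= membership:
            seeds.append(group)

    # iterative merge: any two groups sharing > 50% of the smaller's members
    merged = True
    while merged:
        merged = False
        for i in range(len(seeds)):
            for j in range(i + 1, len(seeds)):
                overlap = len(seeds[i] & seeds[j])
                if overlap > 0.5 * min(len(seeds[i]), len(seeds[j])):
                    seeds[i] = seeds[i] | seeds[j]
                    del seeds[j]
                    merged = True
                    break
            if merged:
                break

    # deduplicate identical groups, deterministic order
    unique = sorted({tuple(sorted(g)) for g in seeds})
    clusters = []
    clustered: set[str] = set()
    for members in unique:
        if p_values:
            rep = min(members, key=lambda t: (p_values.get(t, 1.0), t))
        else:
            rep = members[0]
        clusters.append(TermCluster(members=members, representative=rep))
        clustered.update(members)
    unclustered = [t for t in ids if t not in clustered]
    return clusters, unclustered


# ---------------------------------------------------------------------------
# I/O

def read_gmt(path: str | Path) -> list[AnnotationTerm]:
    """Read tab-delimited GMT: term_id, description, genes...

    The description field optionally carries the category as a ``CC:``/
    ``BP:``/``MF:`` prefix (e.g. ``BP:apoptotic process``); terms without a
    prefix get category ``NA``.
    """
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        term_id, desc = fields[0], fields[1]
        if ":" in desc and desc.split(":", 1)[0] in {"CC", "BP", "MF"}:
            category, name = desc.split(":", 1)
        else:
            category, name = "NA", desc
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        terms.append(AnnotationTerm(term_id, name, category, genes))
    return terms


def write_gmt(terms: Iterable[AnnotationTerm], path: str | Path) -> None:
    lines = []
    for t in terms:
        desc = f"{t.category}:{t.name}" if t.category != "NA" else t.name
        lines.append("\t".join([t.term_id, desc, *sorted(t.genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "fdr": r.fdr,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def write_cluster_table(
    clusters: Sequence[TermCluster], unclustered: Sequence[str], path: str | Path
) -> None:
    import pandas as pd

    rows = [
        {
            "cluster": i + 1,
            "representative": c.representative,
            "n_terms": len(c.members),
            "members": ",".join(c.members),
        }
        for i, c in enumerate(clusters)
    ]
    if unclustered:
        rows.append(
            {
                "cluster": 0,
                "representative": "",
                "n_terms": len(unclustered),
                "members": ",".join(unclustered),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
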