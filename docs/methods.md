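# Methods

This note documents the models and procedures implemented in `proteonet`,
the parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Quantification and differential classification

Abundance is the exponentially modified protein abundance index,
`emPAI = 10^(n_observed/n_observable) − 1`. It is a per-protein, label-free
proxy for molar amount; it is dimensionless, zero exactly when no peptide
was sequenced, and strictly increasing in the observed-peptide count.
Replicates are merged by the arithmetic mean over replicates in which the
protein was detected (value > 0); a mean-over-all-replicates mode is
available (`merge_mode="all"`) since the right choice depends on whether an
absence is a true zero or a missed identification. Proteins are keyed by
canonical uppercase gene symbol because all downstream joins (interactions,
annotations) are symbol-level; collisions after normalization keep the
max-emPAI record and warn.

The signed fold-change of a shared protein is the ratio of the larger to
the smaller merged abundance, negative when the second condition is higher,
so |fold| ≥ 1 always; ties are +1 by convention (arbitrary but fixed and
tested). Classification at threshold t (default 2, must be > 1) is strict:
`over` iff fold > t, `under` iff fold < −t. Cell-line-specific proteins
have no finite fold and are handled by the set partition, not the
classifier; a shared protein quantified as zero on either side is treated
as a data error rather than silently imputed.

Replicate agreement is the mean pairwise Pearson r between replicate
columns (zero-variance columns skipped with a warning). "Dynamic range" has
no universally agreed definition for emPAI profiles; we report
log2(max/min) as the headline value together with the raw ratio and the
log10 variant, and make no claim of comparability with other definitions.
Because the three-way classification at threshold 2 need not match a
"similar amounts" narrative count, the pipeline additionally reports counts
per |fold| band (1–1.5, 1.5–2, > 2).

## Term enrichment and clustering

Enrichment of a query set against a term is the exact right tail
P(X ≥ k) of the hypergeometric distribution (scipy's `hypergeom.sf(k−1)`),
never a normal approximation; term genes are intersected with the declared
background first, and the background defaults to all proteins detected in
either cell line. Benjamini–Hochberg adjustment is applied per query across
all tested terms. The default filter keeps terms with ≥ 3 query hits and
raw p ≤ 0.05 (DAVID-style); an FDR < 0.05 mode (ClueGO-style) is a flag. An
EASE-style variant (k−1 in the tail) is deliberately not the default — the
plain hypergeometric is the canonical statistic; small-term discreteness
already makes it conservative, which is why the type-I calibration test
measures the null rejection rate in a regime (background 1000, query 200,
terms of 50–200 genes) where the discrete tail can actually resolve the 5%
level; with very small terms the simulated rate falls to 2–3% by
discreteness alone.

Term–term similarity is Cohen's κ on the 2×2 gene-membership table over the
background, computed in closed form from the four counts. When expected
agreement is exactly 1 the statistic is undefined; we define it as 1 for
identical sets and 0 otherwise, with a warning. Clustering follows the
DAVID heuristic: seed groups are each term with its κ ≥ threshold
neighbours, retained at size ≥ the membership parameter (default 2), then
merged while any two groups share > 50% of the smaller one's members. The
κ threshold is a per-run parameter in [0.3, 0.45] because the appropriate
stringency varies with the ontology branch. Tie-breaks are lexicographic on
term id, so the clustering is deterministic.

## Interaction networks and topology

Edges carry a confidence score in [0, 1]; the score cutoff (0.63 medium /
0.73 high) is inclusive, matching the quartile-style cutoffs of
HIPPIE-like resources. The context filter keeps a candidate interactor only
if it appears in ≥ 2 (configurable) independent expression sources;
MS-detected proteins bypass it because their detection is direct evidence
of expression. Assembly drops self-loops, collapses duplicate pairs to the
maximum score, and by default keeps only edges with at least one detected
endpoint (a first-neighbour network); interactor–interactor edges among
already-included nodes can be kept with a flag, since published practice is
ambiguous on this point.

Degree is the raw edge count. Betweenness is Brandes' exact algorithm on
the unweighted graph, computed and normalized per connected component by
(n−1)(n−2)/2 with n the component size — the NetworkAnalyzer convention
that keeps printed values in [0, 1]. Hub calls use degree ≥ 10 inclusive:
nominally the published cutoff is "> 10", but the published flag table
marks degree-10 nodes as hubs, so the inclusive reading is the one
consistent with the evidence. Bottleneck calls stay strict (> 0.3), which
no printed row contradicts.

## Prize-collecting Steiner integration

The instance maps proteomics onto prizes and confidence onto costs:
`prize(v) = β·max(1, |log2 fold(v)|)` for detected proteins (the floor
keeps unaltered detected proteins as genuine terminals, since published
terminal counts correspond to full MS lists), `β·2` for cell-line-specific
proteins (no finite fold; a fixed moderate prize), 0 for interactors;
`cost(e) = −ln(score)` floored at ε = 1e−6 (a `1 − score + ε` linear mode
is kept for sensitivity analyses). The objective is the standard unrooted
Goemans–Williamson form: excluded-terminal prizes plus tree-edge costs.

The exact solver enumerates connected node subsets and takes the minimum
spanning tree of each induced subgraph — exhaustive over trees because the
cheapest tree spanning a fixed node set is that subset's MST. It is the
default up to 12 nodes. Above that, the heuristic builds candidate trees
per connected component — the metric-closure Steiner-tree approximation
over the component's terminals, repeated over a sweep of up to 8 prize
thresholds (dropping low-prize terminals changes the tree shape), plus the
component MST — and strong-prunes each: a rooted dynamic program,
`net(v) = prize(v) + Σ_children max(0, net(c) − cost(v,c))`, evaluated from
every root, which returns the optimal subtree of a fixed tree. The best
candidate is compared against every single-terminal tree, so the heuristic
can never be worse than excluding all terminals, and returned trees never
contain a leaf whose prize is below its attachment cost. On random
10-node/15-edge instances the heuristic matches the exact optimum about
95% of the time with worst-case excess around 6% (measured in the test
suite). Ties are broken lexicographically on node ids, making both solvers
deterministic.

## Synthetic data generator

Defaults reproduce the study design: proteomes of 735 and 789 proteins with
496 shared; 3 replicates with 10% multiplicative (log-normal) CV; planted
signed folds of |4| on 68/496 (over) and 83/496 (under) of the shared set,
with the remainder jittering uniformly within ±0.5 log2 units so that the
planted classification is recoverable at threshold 2; base abundances
log-normal (μ = ln 0.4, σ = 1.2 in ln units), sized to give the several
orders of magnitude of dynamic range typical of label-free data. The
interactome backbone is preferential attachment (2 edges per node) over the
detected proteins plus 300 undetected interactors with Beta(4, 2)
confidence scores (mean 2/3, mimicking a medium/high-confidence resource),
plus three planted structures recorded in a truth manifest: a 30-spoke star
hub, a bridge node joining two 10-cliques (highest betweenness in its
component by construction), and a cheap-edge star over six high-prize
terminals with expensive decoy edges, whose optimal PCST solution is the
planted tree. Expression sources include each gene independently with
probability 0.5 across 5 sources; annotation terms number 50 (sizes 10–60)
with 5 planted to draw 80% of their genes from a designated query.

What the generator does not emulate: peptide-level identification and its
error structure (the written peptide counts are a consistent integer
stand-in; the emPAI column is authoritative), missing-at-random dropout
across replicates (every protein of a profile appears in all its
replicates, which is why synthetic replicate Pearson r is ≈ 0.99 rather
than the ≈ 0.88 of real data), literal gene symbols, the empirical degree
distribution and score-evidence correlation of curated interaction
databases, and ontology hierarchy (terms are flat sets). Passing tests
therefore demonstrate correctness of the algorithms and the calibration
claimed above, not robustness to real-data pathologies such as batch
effects or identification errors.

Determinism: all randomness flows from `numpy.random.default_rng` seeded
per stage as `[seed, stage]`; a fixed seed yields byte-identical output
files.

## Problem sizes and test design

Unit and pipeline tests run on a scaled-down design (90/100 proteomes,
60 shared; 40 extra interactors) so the full suite stays fast; the
partition/differential calibration checks and the planted-fold recovery
test run at the full 735/789 design, which the generator produces in well
under a second. Oracles are independent by construction: betweenness is
checked against explicit shortest-path enumeration, the exact PCST solver
against edge-subset enumeration, the hypergeometric tail against rational
arithmetic with `math.comb`, BH against hand-computed step-up values, and
κ against scikit-learn's `cohen_kappa_score` on materialized membership
vectors.

## Known limitations

* The heuristic PCST solver is an approximation without a worst-case
  guarantee; its quality is characterized empirically on small instances.
* Weighted betweenness (using scores as distances) is available but the
  hub/bottleneck semantics are defined on the unweighted convention.
* The enrichment module does no ontology-aware redundancy reduction (no
  term-hierarchy fusion); κ clustering is its only redundancy control.
* Accession-to-symbol mapping is the caller's responsibility beyond case
  normalization; no identifier service is consulted.
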