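"""Hypergeometric enrichment, BH adjustment, kappa clustering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import hypergeom_tail_oracle
from proteonet.enrich import (
    AnnotationTerm,
    bh_fdr,
    cluster_terms,
    enrich_query,
    filter_terms,
    hypergeom_enrichment,
    kappa_similarity,
    read_gmt,
    write_gmt,
)
from proteonet.synthetic import SimulationConfig, generate_annotations


def _term(term_id, genes, category="BP"):
    return AnnotationTerm(term_id, term_id.lower(), category, frozenset(genes))


BACKGROUND20 = {f"G{i:02d}" for i in range(20)}


class TestHypergeom:
    def test_zero_hits_gives_one(self):
        term = _term("T1", {"G10", "G11"})
        res = hypergeom_enrichment({"G00", "G01"}, term, BACKGROUND20)
        assert res.k == 0 and res.p_value == 1.0

    def test_query_equals_background_gives_one(self):
        term = _term("T1", {"G00", "G01", "G02"})
        res = hypergeom_enrichment(set(BACKGROUND20), term, BACKGROUND20)
        assert res.k == res.K and res.p_value == pytest.approx(1.0)

    def test_full_overlap_matches_exact_fraction(self):
        # N=20, K=5, n=10, k=5 -> C(15,5)/C(20,10) = 3003/184756
        genes = {f"G{i:02d}" for i in range(5)}
        query = {f"G{i:02d}" for i in range(10)}
        res = hypergeom_enrichment(query, _term("T1", genes), BACKGROUND20)
        assert res.p_value == pytest.approx(3003 / 184756, rel=1e-12)

    @pytest.mark.parametrize("N", [5, 10, 17, 25])
    def test_exact_tail_matches_rational_oracle(self, N):
        background = {f"G{i:02d}" for i in range(N)}
        rng = np.random.default_rng(N)
        for _ in range(10):
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term_genes = set(rng.choice(sorted(background), size=K, replace=False))
            query = set(rng.choice(sorted(background), size=n, replace=False))
            res = hypergeom_enrichment(query, _term("T", term_genes), background)
            expected = float(hypergeom_tail_oracle(res.k, N, K, n))
            assert res.p_value == pytest.approx(expected, rel=1e-10)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(set(), _term("T", {"G00"}), BACKGROUND20)
        with pytest.raises(ValueError):
            hypergeom_enrichment({"G00"}, _term("T", {"G00"}), set())

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"NOPE"}, _term("T", {"G00"}), BACKGROUND20)


class TestBH:
    def test_single_value_unchanged(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_hand_stepup_example(self):
        assert bh_fdr([0.005, 0.01, 0.03, 0.04]) == pytest.approx(
            [0.02, 0.02, 0.04, 0.04]
        )

    def test_all_equal_stay_equal(self):
        assert bh_fdr([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    @given(
        ps=st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=2, max_size=30),
        seed=st.integers(0, 100),
    )
    def test_permutation_equivariant_and_dominates_p(self, ps, seed):
        perm = np.random.default_rng(seed).permutation(len(ps))
        adj = bh_fdr(ps)
        adj_perm = bh_fdr([ps[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])
        assert all(q >= p - 1e-12 for p, q in zip(ps, adj))


class TestFilterTerms:
    def test_gene_threshold_removes_small_terms(self):
        background = {f"G{i:03d}" for i in range(100)}
        query = {f"G{i:03d}" for i in range(10)}
        tiny = _term("TINY", {"G000", "G001"})       # k=2, very enriched
        mid = _term("MID", {f"G{i:03d}" for i in range(5)})  # k=5
        results = enrich_query(query, [tiny, mid], background)
        kept = filter_terms(results, min_genes=3, alpha=0.05)
        assert [r.term_id for r in kept] == ["MID"]

    def test_planted_terms_exactly_recovered(self):
        """With 5 terms planted to oversample the query, the FDR filter keeps
        exactly the planted terms among 50."""
        cfg = SimulationConfig(
            seed=2, n_terms=50, n_planted_enriched=5, term_size_range=(10, 30)
        )
        background = [f"G{i:03d}" for i in range(300)]
        query = background[:40]
        terms, planted = generate_annotations(cfg, background, query)
        results = enrich_query(set(query), terms, set(background))
        kept = filter_terms(results, min_genes=3, alpha=0.05, use_fdr=True)
        assert {r.term_id for r in kept} == planted


class TestKappa:
    BG100 = {f"G{i:03d}" for i in range(100)}

    def test_identical_sets(self):
        s = {f"G{i:03d}" for i in range(10)}
        assert kappa_similarity(s, s, self.BG100) == pytest.approx(1.0)

    def test_disjoint_sets_hand_value(self):
        a = {f"G{i:03d}" for i in range(10)}
        b = {f"G{i:03d}" for i in range(10, 20)}
        # observed agreement 0.80, expected 0.82 -> kappa = -0.02/0.18
        assert kappa_similarity(a, b, self.BG100) == pytest.approx(-1 / 9)

    def test_degenerate_background_equal_sets(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert kappa_similarity(self.BG100, self.BG100, self.BG100) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sklearn_on_membership_vectors(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        bg = sorted(self.BG100)
        a = set(rng.choice(bg, size=30, replace=False))
        b = set(rng.choice(bg, size=45, replace=False))
        va = [g in a for g in bg]
        vb = [g in b for g in bg]
        expected = sklearn_metrics.cohen_kappa_score(va, vb)
        assert kappa_similarity(a, b, self.BG100) == pytest.approx(expected)
        assert kappa_similarity(b, a, self.BG100) == pytest.approx(expected)


class TestClusterTerms:
    BG = {f"G{i:03d}" for i in range(100)}

    def test_two_identical_terms_form_one_cluster(self):
        genes = {f"G{i:03d}" for i in range(12)}
        terms = [_term("TA", genes), _term("TB", genes)]
        clusters, unclustered = cluster_terms(terms, self.BG, kappa_threshold=0.35)
        assert len(clusters) == 1 and clusters[0].members == ("TA", "TB")
        assert unclustered == []

    def test_all_dissimilar_terms_stay_unclustered(self):
        terms = [
            _term(f"T{j}", {f"G{(20 * j + i):03d}" for i in range(5)})
            for j in range(4)
        ]
        clusters, unclustered = cluster_terms(terms, self.BG, kappa_threshold=0.35)
        assert clusters == [] and len(unclustered) == 4

    def test_two_planted_blocks_recovered(self):
        """Six terms built as two high-overlap blocks cluster into exactly
        the blocks; verified against brute-force pairwise kappa."""
        block1 = [f"G{i:03d}" for i in range(20)]
        block2 = [f"G{i:03d}" for i in range(50, 70)]
        terms = []
        for j in range(3):  # within-block overlap 16/20
            terms.append(_term(f"A{j}", set(block1[j * 2 : j * 2 + 16])))
            terms.append(_term(f"B{j}", set(block2[j * 2 : j * 2 + 16])))
        # construction check: within-block kappa high, between-block low
        for j in range(3):
            for k in range(j + 1, 3):
                assert kappa_similarity(terms[2 * j].genes, terms[2 * k].genes, self.BG) > 0.45
                assert kappa_similarity(terms[2 * j].genes, terms[2 * k + 1].genes, self.BG) < 0.0
        clusters, unclustered = cluster_terms(terms, self.BG, kappa_threshold=0.45)
        assert {c.members for c in clusters} == {("A0", "A1", "A2"), ("B0", "B1", "B2")}
        assert unclustered == []

    def test_deterministic_and_lowest_p_representative(self):
        genes = {f"G{i:03d}" for i in range(12)}
        terms = [_term("TB", genes), _term("TA", genes)]
        pvals = {"TA": 0.04, "TB": 0.001}
        out1 = cluster_terms(terms, self.BG, p_values=pvals)
        out2 = cluster_terms(list(reversed(terms)), self.BG, p_values=pvals)
        assert out1 == out2
        assert out1[0][0].representative == "TB"


class TestGmtIO:
    def test_round_trip_preserves_terms(self, tmp_path):
        terms = [
            _term("T1", {"AAA", "BBB", "CCC"}, category="CC"),
            _term("T2", {"BBB", "DDD"}, category="MF"),
        ]
        path = tmp_path / "terms.gmt"
        write_gmt(terms, path)
        back = read_gmt(path)
        assert back == terms

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("T1\tonly-description\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(path)
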