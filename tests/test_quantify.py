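"""emPAI computation, replicate merging, partitioning, fold classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import partition_oracle
from proteonet.quantify import (
    ProteomeProfile,
    classify_differential,
    compare_profiles,
    compute_empai,
    dynamic_range,
    fold_change,
    merge_replicates,
    partition,
    replicate_pearson,
)
from proteonet.synthetic import SimulationConfig, generate_proteomes


class TestEmpai:
    @pytest.mark.parametrize(
        "observed, observable, expected",
        [
            (0, 10, 0.0),
            (10, 10, 9.0),
            # 10**(3/10) - 1, frozen from an arbitrary-precision evaluation
            (3, 10, 0.9952623149688795),
        ],
    )
    def test_known_values(self, observed, observable, expected):
        assert compute_empai(observed, observable) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("observed, observable", [(1, 0), (-1, 10), (2, -3)])
    def test_invalid_counts_rejected(self, observed, observable):
        with pytest.raises(ValueError):
            compute_empai(observed, observable)

    @given(observable=st.integers(1, 50), observed=st.integers(0, 49))
    def test_strictly_monotone_in_observed(self, observable, observed):
        assert compute_empai(observed + 1, observable) > compute_empai(observed, observable)

    def test_zero_iff_no_observed_peptides(self):
        for observable in (1, 7, 100):
            assert compute_empai(0, observable) == 0.0
            assert compute_empai(1, observable) > 0.0


class TestMergeReplicates:
    def test_constant_and_mean(self):
        assert merge_replicates([2.0, 2.0, 2.0]) == 2.0
        assert merge_replicates([1.0, 3.0]) == 2.0

    def test_detected_only_vs_all_modes(self):
        values = [0.0, 1.0, 2.0]
        assert merge_replicates(values, mode="detected") == pytest.approx(1.5)
        assert merge_replicates(values, mode="all") == pytest.approx(1.0)

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValueError):
            merge_replicates([])
        with pytest.raises(ValueError):
            merge_replicates([1.0, -0.5])


class TestFoldChange:
    def test_published_worked_examples(self):
        # printed per-cell-line emPAI pairs and their printed folds
        assert round(fold_change(1.32, 5.62), 2) == -4.26
        # the printed -5.11 comes from unrounded abundances; 1% tolerance
        assert fold_change(0.48, 2.45) == pytest.approx(-5.11, rel=0.01)

    def test_equal_abundances_positive_one(self):
        assert fold_change(2.0, 2.0) == 1.0

    @pytest.mark.parametrize("a, b", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_nonpositive_rejected(self, a, b):
        with pytest.raises(ValueError):
            fold_change(a, b)

    @given(
        a=st.floats(0.01, 100, allow_nan=False),
        b=st.floats(0.01, 100, allow_nan=False),
    )
    def test_antisymmetric_and_at_least_one(self, a, b):
        f_ab, f_ba = fold_change(a, b), fold_change(b, a)
        assert abs(f_ab) >= 1.0
        if a != b:
            assert f_ab == pytest.approx(-f_ba)


class TestClassify:
    @pytest.mark.parametrize(
        "fold, expected",
        [(13.58, "over"), (-8.03, "under"), (1.0, "unaltered"), (2.0, "unaltered"),
         (-2.0, "unaltered"), (2.0001, "over")],
    )
    def test_labels(self, fold, expected):
        assert classify_differential(fold) == expected

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_differential(3.0, threshold=1.0)

    @given(
        folds=st.lists(st.floats(1.0, 50.0), min_size=1, max_size=50),
        signs=st.lists(st.sampled_from([1, -1]), min_size=1, max_size=50),
        threshold=st.floats(1.1, 10.0),
    )
    def test_three_way_counts_sum(self, folds, signs, threshold):
        signed = [s * f for s, f in zip(folds, signs)]
        labels = [classify_differential(f, threshold) for f in signed]
        assert sum(labels.count(l) for l in ("over", "under", "unaltered")) == len(signed)


def _profile(name, accessions):
    return ProteomeProfile(name, {a: 1.0 for a in accessions})


class TestPartition:
    def test_identical_profiles(self):
        p = _profile("X", ["P1", "P2", "P3"])
        res = partition(p, _profile("Y", ["P1", "P2", "P3"]))
        assert res.counts == {
            "total_a": 3, "total_b": 3, "shared": 3, "specific_a": 0, "specific_b": 0
        }

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"G{i:03d}" for i in range(120)]
        a = set(rng.choice(universe, size=50, replace=False))
        b = set(rng.choice(universe, size=50, replace=False))
        res = partition(_profile("A", a), _profile("B", b))
        shared, only_a, only_b = partition_oracle(a, b)
        assert (set(res.shared), set(res.specific_a), set(res.specific_b)) == (
            shared, only_a, only_b
        )

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            partition(ProteomeProfile("A", {}), _profile("B", ["P1"]))

    def test_study_scale_counts(self, study_scale_proteomes):
        profile_a, profile_b, _ = study_scale_proteomes
        res = partition(profile_a, profile_b)
        assert res.counts == {
            "total_a": 735, "total_b": 789, "shared": 496,
            "specific_a": 239, "specific_b": 293,
        }


class TestReplicatePearson:
    def test_identical_columns(self):
        mat = pd.DataFrame({"r1": [1.0, 2.0, 3.0], "r2": [1.0, 2.0, 3.0]})
        assert replicate_pearson(mat) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        mat = pd.DataFrame({"r1": [1.0, 2.0, 3.0], "r2": [3.0, 2.0, 1.0]})
        assert replicate_pearson(mat) == pytest.approx(-1.0)

    def test_constant_column_skipped_with_warning(self):
        mat = pd.DataFrame(
            {"r1": [1.0, 2.0, 3.0], "r2": [5.0, 5.0, 5.0], "r3": [1.0, 2.0, 4.0]}
        )
        with pytest.warns(UserWarning, match="zero variance"):
            r = replicate_pearson(mat)
        assert -1.0 <= r <= 1.0

    def test_all_pairs_skipped_is_error(self):
        mat = pd.DataFrame({"r1": [1.0, 1.0, 1.0], "r2": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                replicate_pearson(mat)

    def test_recovers_generated_correlation(self):
        # 3 replicates drawn with pairwise correlation 0.9 over 200 proteins
        rng = np.random.default_rng(3)
        cov = np.full((3, 3), 0.9)
        np.fill_diagonal(cov, 1.0)
        mat = pd.DataFrame(rng.multivariate_normal(np.zeros(3), cov, size=200) + 10)
        assert replicate_pearson(mat) == pytest.approx(0.9, abs=0.05)


class TestDynamicRange:
    def test_flat_profile_is_zero(self):
        p = _profile("X", ["P1", "P2", "P3"])
        assert dynamic_range(p)["log2"] == 0.0

    def test_log2_of_ratio(self):
        p = ProteomeProfile("X", {"P1": 8.0, "P2": 0.5, "P3": 1.0})
        out = dynamic_range(p)
        assert out["log2"] == pytest.approx(4.0)
        assert out["ratio"] == pytest.approx(16.0)

    def test_span_three_decades(self):
        values = np.geomspace(0.01, 10.24, num=30)
        p = ProteomeProfile("X", {f"P{i}": float(v) for i, v in enumerate(values)})
        assert dynamic_range(p)["log2"] == pytest.approx(10.0)

    def test_zero_excluded_with_warning(self):
        p = ProteomeProfile("X", {"P1": 0.0, "P2": 1.0, "P3": 4.0})
        with pytest.warns(UserWarning, match="excluded"):
            assert dynamic_range(p)["log2"] == pytest.approx(2.0)


class TestPlantedFoldRecovery:
    def test_planted_fold4_recovered_at_threshold2(self):
        """>= 95% of proteins planted at |fold| = 4 with 10% replicate CV
        classify as over/under at threshold 2."""
        cfg = SimulationConfig(
            seed=21, n_proteins_a=300, n_proteins_b=320,
            overlap_fraction=200 / 300,
            planted_folds=((0.1, 4.0), (0.1, -4.0)),
            replicate_cv=0.10,
        )
        profile_a, profile_b, truth = generate_proteomes(cfg)
        records = {r.accession: r for r in compare_profiles(profile_a, profile_b)}
        planted = truth[truth["true_label"].isin(["over", "under"])]
        assert len(planted) == 40
        hits = sum(
            records[row.accession].label == row.true_label
            for row in planted.itertuples()
        )
        assert hits / len(planted) >= 0.95
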