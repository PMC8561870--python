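import numpy as np
import pandas as pd
import pytest

from singlefiber import (
    Pattern,
    classify_all,
    classify_pattern,
    group_medians,
    tabulate_patterns,
)

from conftest import make_matrix


def summary(m1, m2a, m2x, n1=10, n2a=10, n2x=10):
    return {
        "protein_id": "P1",
        "median_1": m1, "median_2a": m2a, "median_2x": m2x,
        "n_valid_1": n1, "n_valid_2a": n2a, "n_valid_2x": n2x,
    }


def diff(significant=True, tested=True, t_1_2a=0.001, t_1_2x=0.001, t_2a_2x=0.001):
    return {
        "tested": tested,
        "fdr_significant": significant,
        "tukey_p_1_2a": t_1_2a,
        "tukey_p_1_2x": t_1_2x,
        "tukey_p_2a_2x": t_2a_2x,
    }


class TestGroupMedians:
    def test_median_and_pct_of_max(self):
        matrix = make_matrix(
            [
                [2.0, 4.0, 6.0, 5.0, 5.0, 2.5, 2.5],
                [10.0, 10.0, 10.0, 5.0, 5.0, 2.5, 2.5],
            ],
            ["1", "1", "1", "2A", "2A", "2X", "2X"],
        )
        out = group_medians(matrix)
        assert out.loc["P1", "median_1"] == 4.0
        np.testing.assert_allclose(
            out.loc["P2", ["pct_1", "pct_2a", "pct_2x"]], [100.0, 50.0, 25.0]
        )

    def test_undefined_group_median(self):
        matrix = make_matrix(
            [[np.nan, np.nan, 8.0, 8.0, 2.0, 2.0]],
            ["1", "1", "2A", "2A", "2X", "2X"],
        )
        out = group_medians(matrix)
        assert np.isnan(out.loc["P1", "median_1"])
        assert np.isnan(out.loc["P1", "pct_1"])
        np.testing.assert_allclose(out.loc["P1", ["pct_2a", "pct_2x"]], [100.0, 25.0])

    def test_all_missing_protein_excluded_with_warning(self):
        matrix = make_matrix(
            [[np.nan] * 4, [1.0, 2.0, 3.0, 4.0]], ["1", "1", "2A", "2X"]
        )
        with pytest.warns(UserWarning, match="no valid values"):
            out = group_medians(matrix)
        assert list(out.index) == ["P2"]


class TestClassifyPattern:
    def test_type1_specific(self):
        call = classify_pattern(summary(90, 10, 8), diff())
        assert call.pattern is Pattern.TYPE1_SPECIFIC
        assert call.rule_trace == ("R1",)

    def test_gradient_down(self):
        call = classify_pattern(summary(10, 7, 4), diff())
        assert call.pattern is Pattern.GRAD_1_2A_2X
        assert call.rule_trace[-1] == "R6"

    def test_gradient_up(self):
        call = classify_pattern(summary(4, 7, 10), diff())
        assert call.pattern is Pattern.GRAD_2X_2A_1

    def test_type2_specific(self):
        call = classify_pattern(summary(3, 10, 9.5), diff())
        assert call.pattern is Pattern.TYPE2_SPECIFIC

    def test_type1_2a_specific(self):
        call = classify_pattern(summary(10, 9.5, 3), diff())
        assert call.pattern is Pattern.TYPE1_2A_SPECIFIC

    def test_atypical_low_2a_is_minor(self):
        call = classify_pattern(summary(10, 2, 9), diff())
        assert call.pattern is Pattern.MINOR

    def test_specificity_beats_gradient(self):
        # 30/6/2 satisfies both R1 (>=3-fold over both) and the R6 ordering
        call = classify_pattern(summary(30, 6, 2), diff())
        assert call.pattern is Pattern.TYPE1_SPECIFIC

    def test_not_significant_and_not_tested(self):
        assert classify_pattern(summary(90, 10, 8), diff(significant=False)).pattern \
            is Pattern.NOT_SIGNIFICANT
        assert classify_pattern(summary(90, 10, 8), diff(tested=False)).pattern \
            is Pattern.NOT_TESTED

    def test_gradient_requires_pairwise_significance(self):
        call = classify_pattern(summary(10, 7, 4), diff(t_1_2x=0.2))
        assert call.pattern is Pattern.MINOR

    def test_specific_requires_both_tukey_pairs(self):
        call = classify_pattern(summary(90, 10, 8), diff(t_1_2a=0.2))
        assert call.pattern is not Pattern.TYPE1_SPECIFIC

    def test_undefined_denominator_needs_enough_valid_values(self):
        # absent in 2A/2X: ratio passes only when the type-1 group has >= 4 values
        marker = summary(90, np.nan, np.nan, n1=10, n2a=0, n2x=0)
        assert classify_pattern(marker, diff()).pattern is Pattern.TYPE1_SPECIFIC
        sparse = summary(90, np.nan, np.nan, n1=3, n2a=0, n2x=0)
        assert classify_pattern(sparse, diff()).pattern is not Pattern.TYPE1_SPECIFIC

    def test_boundary_fold_inclusive(self):
        # exactly 3-fold counts ("at least 3-fold")
        call = classify_pattern(summary(9.0, 3.0, 3.0), diff())
        assert call.pattern is Pattern.TYPE1_SPECIFIC

    @pytest.mark.parametrize("seed", range(3))
    def test_exactly_one_pattern_and_fold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        specific = {
            Pattern.TYPE1_SPECIFIC, Pattern.TYPE2A_SPECIFIC, Pattern.TYPE2X_SPECIFIC,
            Pattern.TYPE2_SPECIFIC, Pattern.TYPE1_2A_SPECIFIC,
        }
        for _ in range(200):
            s = summary(*rng.lognormal(0, 2, size=3))
            d = diff(
                t_1_2a=rng.uniform(0, 0.2),
                t_1_2x=rng.uniform(0, 0.2),
                t_2a_2x=rng.uniform(0, 0.2),
            )
            call3 = classify_pattern(s, d, fold_threshold=3.0)
            call2 = classify_pattern(s, d, fold_threshold=1.5)
            assert isinstance(call3.pattern, Pattern)  # total function
            if call3.pattern in specific:
                # lowering the fold threshold keeps a specific label specific
                assert call2.pattern in specific


class TestTabulate:
    def test_empty_input_gives_zero_counts(self):
        counts = tabulate_patterns([])
        assert all(v == 0 for v in counts.values())

    def test_major_total_excludes_2a_and_1_2a(self):
        calls = [
            Pattern.TYPE1_SPECIFIC, Pattern.TYPE2A_SPECIFIC, Pattern.TYPE2X_SPECIFIC,
            Pattern.TYPE2_SPECIFIC, Pattern.TYPE1_2A_SPECIFIC, Pattern.GRAD_1_2A_2X,
            Pattern.GRAD_2X_2A_1, Pattern.MINOR, Pattern.NOT_SIGNIFICANT,
        ]
        counts = tabulate_patterns(calls)
        assert counts["major_total"] == 5
        assert counts["significant_total"] == 8

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        calls = list(rng.choice([p.value for p in Pattern], size=50))
        shuffled = list(calls)
        rng.shuffle(shuffled)
        assert tabulate_patterns(calls) == tabulate_patterns(shuffled)


class TestScaleInvariance:
    def test_global_scaling_leaves_calls_unchanged(self, small_sim):
        from singlefiber import FdrConfig, differential_analysis
        from singlefiber.normalization import NormalizedMatrix

        matrix, _ = small_sim
        diff_result = differential_analysis(matrix, FdrConfig(n_permutations=25, seed=2))
        calls = classify_all(group_medians(matrix), diff_result)
        scaled = NormalizedMatrix(
            values=matrix.values * 37.5,
            gene_names=matrix.gene_names,
            fiber_types=matrix.fiber_types,
        )
        calls_scaled = classify_all(group_medians(scaled), diff_result)
        pd.testing.assert_frame_equal(calls, calls_scaled)
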