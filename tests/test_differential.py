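import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from singlefiber import (
    FdrConfig,
    anova_f,
    differential_analysis,
    pairwise_volcano,
    permutation_fdr,
    tukey_hsd,
)
from singlefiber.differential import studentized_range_sf

from conftest import make_matrix
from oracles import anova_f_bruteforce


def random_groups(rng, sizes=(10, 10, 10)):
    return [rng.normal(rng.uniform(-1, 1), rng.uniform(0.2, 2), n) for n in sizes]


class TestAnovaF:
    def test_identical_groups_give_zero_f(self):
        f, p = anova_f([(1, 2, 3), (1, 2, 3), (1, 2, 3)])
        assert f == 0.0
        assert p == 1.0

    def test_zero_within_variance_gives_infinite_f(self):
        f, p = anova_f([(0, 0), (1, 1), (2, 2)])
        assert np.isinf(f)
        assert p == 0.0

    def test_untestable_returns_nan_marker(self):
        f, p = anova_f([(1.0,), (2.0,), (1, 2)])
        assert np.isnan(f) and np.isnan(p)

    def test_small_groups_dropped_from_test(self):
        # third group has a single value: ANOVA runs on the other two
        f, p = anova_f([(1, 2, 3), (4, 5, 6), (100.0,)])
        f2, p2 = anova_f([(1, 2, 3), (4, 5, 6)])
        assert f == pytest.approx(f2, rel=1e-12)
        assert p == pytest.approx(p2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = random_groups(rng)
        f, p = anova_f(groups)
        f_ref, p_ref = anova_f_bruteforce(groups)
        assert f == pytest.approx(f_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-8)

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
        seed=st.integers(0, 100),
    )
    @settings(deadline=None, max_examples=30)
    def test_location_scale_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        groups = random_groups(rng, sizes=(5, 7, 4))
        f0, _ = anova_f(groups)
        f1, _ = anova_f([g * scale + shift for g in groups])
        assert f1 == pytest.approx(f0, rel=1e-6, abs=1e-9)


class TestStudentizedRange:
    def test_matches_scipy_distribution(self):
        q = np.array([0.2, 1.0, 2.5, 3.5, 5.0, 9.0])
        for k in (2, 3):
            for df in (2, 6, 30, 57):
                np.testing.assert_allclose(
                    studentized_range_sf(q, k, df),
                    stats.studentized_range.sf(q, k, df),
                    atol=1e-9,
                )

    def test_limits(self):
        assert studentized_range_sf(0.0, 3, 10) == 1.0
        assert studentized_range_sf(np.inf, 3, 10) == 0.0


class TestTukey:
    def test_identical_groups_give_p_one(self):
        out = tukey_hsd([(1, 2, 3), (1, 2, 3), (1, 2, 3)])
        for p in out.values():
            assert p >= 0.999

    def test_equal_n_matches_scipy_tukey(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.5, 1.2)]
        ours = tukey_hsd(groups)
        ref = stats.tukey_hsd(*groups)
        for (i, j), p in ours.items():
            assert p == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_unequal_n_kramer_matches_scipy_tukey(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, n) for m, n in ((0, 19), (0.4, 29), (1.0, 13))]
        ours = tukey_hsd(groups)
        ref = stats.tukey_hsd(*groups)
        for (i, j), p in ours.items():
            assert p == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_pair_with_tiny_group_not_tested(self):
        out = tukey_hsd([(1, 2, 3), (4, 5, 6), (7.0,)])
        assert np.isnan(out[(0, 2)]) and np.isnan(out[(1, 2)])
        assert np.isfinite(out[(0, 1)])


class TestPermutationFdr:
    @staticmethod
    def planted_matrix(seed=0, n_null=150, n_effect=12, sizes=(8, 10, 6)):
        rng = np.random.default_rng(seed)
        labels = ["1"] * sizes[0] + ["2A"] * sizes[1] + ["2X"] * sizes[2]
        X = rng.normal(0, 1, size=(n_null + n_effect, len(labels)))
        X[:n_effect, : sizes[0]] += 3.0  # strong type-1 shift
        return X, np.array(labels)

    @staticmethod
    def observed_f(X, labels):
        from singlefiber.differential import _anova_from_sums, _group_sums, _membership

        n, s, q = _group_sums(X, _membership(labels))
        return _anova_from_sums(n, s, q)[0]

    def test_detects_planted_effects_and_is_deterministic(self):
        X, labels = self.planted_matrix()
        f = self.observed_f(X, labels)
        config = FdrConfig(alpha=0.05, n_permutations=100, seed=7)
        flags = permutation_fdr(f, X, labels, config)
        assert flags[:12].all()  # planted effects found
        assert flags[12:].mean() < 0.05
        flags2 = permutation_fdr(f, X, labels, config)
        np.testing.assert_array_equal(flags, flags2)

    def test_significant_set_is_upper_set_of_f(self):
        X, labels = self.planted_matrix(seed=1)
        f = self.observed_f(X, labels)
        flags = permutation_fdr(f, X, labels, FdrConfig(n_permutations=100, seed=1))
        if flags.any():
            threshold = f[flags].min()
            assert (f >= threshold)[flags].all()
            assert not flags[f < threshold].any()

    def test_monotone_in_alpha(self):
        X, labels = self.planted_matrix(seed=2)
        f = self.observed_f(X, labels)
        strict = permutation_fdr(f, X, labels, FdrConfig(alpha=0.05, n_permutations=100, seed=3))
        lax = permutation_fdr(f, X, labels, FdrConfig(alpha=0.5, n_permutations=100, seed=3))
        assert (lax | ~strict).all()  # strict set is a subset of the lax set

    def test_infinite_f_dominates(self):
        X, labels = self.planted_matrix(seed=4)
        f = self.observed_f(X, labels)
        f[20] = np.inf
        flags = permutation_fdr(f, X, labels, FdrConfig(n_permutations=100, seed=4))
        if flags.any():
            assert flags[20]

    def test_single_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 6))
        with pytest.raises(ValueError):
            permutation_fdr(np.ones(5), X, ["1"] * 6, FdrConfig(n_permutations=25))


class TestVolcano:
    def test_identical_groups_give_zero_fc_p_one(self):
        matrix = make_matrix(
            [[1.0, 2.0, 4.0, 1.0, 2.0, 4.0]], ["1", "1", "1", "2A", "2A", "2A"]
        )
        out = pairwise_volcano(matrix, "1", "2A")
        assert out.loc["P1", "log2fc"] == pytest.approx(0.0)
        assert out.loc["P1", "p"] == pytest.approx(1.0)

    def test_swapping_groups_negates_fc(self):
        rng = np.random.default_rng(6)
        matrix = make_matrix(
            rng.lognormal(size=(10, 12)), ["1"] * 6 + ["2A"] * 6
        )
        ab = pairwise_volcano(matrix, "1", "2A")
        ba = pairwise_volcano(matrix, "2A", "1")
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], rtol=1e-12)
        np.testing.assert_allclose(ab["p"], ba["p"], rtol=1e-12)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(7)
        values = rng.lognormal(size=(20, 15))
        matrix = make_matrix(values, ["1"] * 7 + ["2X"] * 8)
        out = pairwise_volcano(matrix, "1", "2X")
        logs = np.log2(values)
        ref = stats.ttest_ind(logs[:, :7], logs[:, 7:], axis=1, equal_var=False)
        np.testing.assert_allclose(out["p"], ref.pvalue, rtol=1e-10)

    def test_underpowered_proteins_omitted(self):
        matrix = make_matrix(
            [[1.0, np.nan, np.nan, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]],
            ["1", "1", "1", "2A", "2A", "2A"],
        )
        out = pairwise_volcano(matrix, "1", "2A")
        assert list(out.index) == ["P2"]

    def test_unknown_type_rejected(self):
        matrix = make_matrix([[1.0, 2.0]], ["1", "2A"])
        with pytest.raises(ValueError):
            pairwise_volcano(matrix, "1", "2B")


class TestDifferentialAnalysis:
    def test_planted_effect_statistics(self, small_sim):
        matrix, truth = small_sim
        result = differential_analysis(matrix, FdrConfig(n_permutations=100, seed=5))
        joined = result.join(truth.proteins["true_pattern"])
        planted = joined[joined["true_pattern"] == "type1_specific"]
        nulls = joined[joined["true_pattern"] == "null"]
        assert planted["fdr_significant"].mean() >= 0.95
        assert nulls["fdr_significant"].mean() <= 0.05
        # fold-8 planted type-1 effect: log2fc(1 vs 2A) close to 3
        assert planted["log2fc_1_2a"].mean() == pytest.approx(3.0, abs=0.5)

    def test_scalar_and_matrix_paths_agree(self, small_sim):
        matrix, _ = small_sim
        result = differential_analysis(matrix, FdrConfig(n_permutations=25, seed=1))
        X = np.log2(matrix.values.to_numpy(dtype=float))
        labels = np.asarray([str(t) for t in matrix.fiber_types])
        rng = np.random.default_rng(0)
        for idx in rng.choice(len(result), size=25, replace=False):
            row = X[idx]
            groups = [row[labels == t][np.isfinite(row[labels == t])] for t in ("1", "2A", "2X")]
            f_ref, p_ref = anova_f(groups)
            tukey_ref = tukey_hsd(groups)
            got = result.iloc[idx]
            if np.isnan(f_ref):
                assert not got["tested"]
                continue
            assert got["F"] == pytest.approx(f_ref, rel=1e-9)
            assert got["p"] == pytest.approx(p_ref, rel=1e-6, abs=1e-12)
            for pair, col in [((0, 1), "tukey_p_1_2a"), ((0, 2), "tukey_p_1_2x"),
                              ((1, 2), "tukey_p_2a_2x")]:
                if np.isnan(tukey_ref[pair]):
                    assert np.isnan(got[col])
                else:
                    assert got[col] == pytest.approx(tukey_ref[pair], rel=1e-6, abs=1e-9)
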