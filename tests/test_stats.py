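"""Nonparametric statistics under SPSS conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from aslkit import (
    bonferroni_posthoc,
    cohort_report,
    friedman,
    mann_whitney_u,
    median_iqr,
    wilcoxon_signed_rank,
)
from aslkit.synthetic import simulate_cohort


class TestMannWhitney:
    def test_full_enumeration_small_case(self):
        r = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == 0.0
        assert r.p == pytest.approx(2.0 / 6.0)

    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = mann_whitney_u(x, x)
        assert r.statistic == len(x) ** 2 / 2
        assert r.p == pytest.approx(1.0)
        assert r.z == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_scipy_oracle(self, rng):
        x, y = rng.standard_normal(8), rng.standard_normal(9)
        r = mann_whitney_u(x, y, mode="exact")
        assert r.p == pytest.approx(sps.mannwhitneyu(x, y, method="exact").pvalue)

    def test_asymptotic_tie_corrected_z(self):
        # hand case with ties: pooled ranks carry one tied pair
        x = [1.0, 2.0, 3.0]
        y = [3.0, 4.0, 5.0]
        r = mann_whitney_u(x, y, mode="asymptotic")
        nx = ny = 3
        u = 0.5  # one tied cross-pair counts half
        var = nx * ny / 12 * ((6 + 1) - (2**3 - 2) / (6 * 5))
        assert r.statistic == pytest.approx(u)
        assert r.z == pytest.approx((u - 4.5) / np.sqrt(var))


class TestWilcoxon:
    def test_nine_all_negative_differences(self):
        pre = np.arange(1.0, 10.0) + np.arange(9) * 0.5 + 10
        post = np.arange(1.0, 10.0)
        r = wilcoxon_signed_rank(pre, post)
        assert r.statistic == 0.0
        assert round(r.z, 2) == -2.67
        assert r.p == pytest.approx(0.0077, abs=5e-4)

    def test_seven_all_negative_differences(self):
        pre = np.linspace(100, 130, 7)
        post = pre - np.linspace(5, 11, 7)
        r = wilcoxon_signed_rank(pre, post)
        assert r.statistic == 0.0
        assert round(r.z, 2) == -2.37

    def test_antisymmetric_differences_give_zero(self):
        pre = np.zeros(4)
        post = np.array([1.0, -2.0, -3.0, 4.0])  # W+ = W− = 5
        r = wilcoxon_signed_rank(pre, post)
        assert r.z == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        post = np.array([1.0, 2.0, 4.5, 6.0, 8.0])  # two zeros drop, n=3
        r = wilcoxon_signed_rank(pre, post)
        assert r.n == (3,)

    def test_too_few_nonzero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.5])

    @given(st.lists(st.floats(0.5, 50), min_size=5, max_size=12, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_antisymmetry_under_sign_flip(self, diffs):
        d = np.asarray(diffs)
        z_pos = wilcoxon_signed_rank(np.zeros_like(d), d).z
        z_neg = wilcoxon_signed_rank(np.zeros_like(d), -d).z
        assert z_pos == pytest.approx(-z_neg)

    def test_matches_scipy_without_continuity(self, rng):
        pre = rng.standard_normal(12)
        post = pre + rng.standard_normal(12)
        r = wilcoxon_signed_rank(pre, post)
        ref = sps.wilcoxon(post, pre, correction=False, mode="approx",
                           zero_method="wilcox")
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestFriedman:
    def test_identical_columns_give_zero(self):
        m = np.tile(np.array([[5.0], [7.0], [9.0]]), (1, 4))
        r = friedman(m)
        assert r.statistic == 0.0
        assert r.p == 1.0

    def test_strictly_increasing_rows_hand_value(self):
        m = np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])
        r = friedman(m)
        assert r.statistic == pytest.approx(6.0)
        assert r.dof == 2
        assert r.p == pytest.approx(sps.chi2.sf(6.0, 2))

    def test_column_permutation_invariance(self, rng):
        m = rng.standard_normal((8, 4))
        base = friedman(m).statistic
        for _ in range(5):
            perm = rng.permutation(4)
            assert friedman(m[:, perm]).statistic == pytest.approx(base)

    def test_matches_scipy_without_ties(self, rng):
        m = rng.standard_normal((10, 4))
        r = friedman(m)
        ref = sps.friedmanchisquare(*m.T)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)

    def test_missing_values_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError):
            friedman(m)


class TestBonferroniAndSummaries:
    def test_consecutive_age_cutoff(self):
        dec = bonferroni_posthoc({"3-6": 0.008, "6-9": 0.5, "9-12": 0.9})
        assert dec["cutoff"].iloc[0] == pytest.approx(0.05 / 3, abs=1e-6)
        assert bool(dec.loc[dec.comparison == "3-6", "significant"].iloc[0])

    def test_trend_below_raw_alpha_not_significant(self):
        dec = bonferroni_posthoc({"3-6": 0.036}, m=3)
        assert not bool(dec["significant"].iloc[0])

    def test_single_comparison_uses_raw_alpha(self):
        dec = bonferroni_posthoc({"only": 0.036}, m=1)
        assert bool(dec["significant"].iloc[0])

    def test_tukey_hinges_one_to_nine(self):
        assert median_iqr(np.arange(1, 10)) == (5.0, 3.0, 7.0)

    def test_single_value_degenerate(self):
        assert median_iqr([4.2]) == (4.2, 4.2, 4.2)

    def test_matches_sort_oracle(self, rng):
        for n in (5, 8, 11, 20):
            v = rng.standard_normal(n)
            med, q1, q3 = median_iqr(v)
            s = np.sort(v)
            half = (n + 1) // 2
            assert med == np.median(s)
            assert q1 == np.median(s[:half])
            assert q3 == np.median(s[n - half:])


class TestCohortReport:
    def test_report_contains_expected_test_families(self):
        df = simulate_cohort(seed=0)
        rep = cohort_report(df)
        assert {
            "mann-whitney genotype",
            "friedman age",
            "wilcoxon age posthoc",
            "wilcoxon anesthesia",
            "wilcoxon att co2",
        } <= set(rep["test"])
        assert rep["p"].between(0, 1).all()

    def test_friedman_uses_complete_cases_only(self):
        df = simulate_cohort(seed=0)
        rep = cohort_report(df)
        fr = rep[(rep.test == "friedman age") & (rep.n.str.contains("TG"))]
        # 7 transgenic mice have all four isoflurane sessions
        assert all(n.startswith("(7, 4)") for n in fr["n"])
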