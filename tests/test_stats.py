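"""Statistical primitives against hand-derived and enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crlmkit.stats import (DegenerateDataWarning, bh_adjust, fisher_exact_2x2,
                           hypergeom_enrich, km_curve, logrank_statistic,
                           logrank_test, median_split, spearman_corr,
                           wilcoxon_rank_sum, wilcoxon_signed_rank)


class TestRankSum:
    def test_symmetric_null_gives_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_fully_separated_small_groups(self):
        # only 2 of C(6,3)=20 rank assignments are as extreme
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.exact

    def test_all_tied_warns_and_returns_one(self):
        with pytest.warns(DegenerateDataWarning):
            res = wilcoxon_rank_sum([1, 1, 1], [1, 1, 1])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_and_asymptotic_branches_agree_on_n8(self):
        # tie-free n=8 per group: continuity-corrected approximation within 0.02
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            exact = wilcoxon_rank_sum(x, y)
            assert exact.exact
            from scipy.stats import mannwhitneyu
            p_asym = mannwhitneyu(x, y, method="asymptotic",
                                  use_continuity=True).pvalue
            assert abs(exact.p_value - p_asym) < 0.02


class TestSignedRank:
    def test_all_positive_differences(self):
        # 2 one-sided extremes out of 2^5 sign assignments
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5]).p_value == pytest.approx(0.0625)

    def test_sign_symmetry(self):
        p_pos = wilcoxon_signed_rank([1, 2, 3, 4, 5]).p_value
        p_neg = wilcoxon_signed_rank([-1, -2, -3, -4, -5]).p_value
        assert p_pos == p_neg

    def test_all_zero_differences_warn(self):
        with pytest.warns(DegenerateDataWarning):
            res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_hand_computed_step_up(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_matches_brute_force_definition(self, p):
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_brute = np.empty(m)
        sorted_p = p[order]
        # q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1
        for i in range(m):
            q_brute[order[i]] = min(
                min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
        assert bh_adjust(p) == pytest.approx(q_brute, abs=1e-12)


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_corr(x, [2, 4, 5, 7, 9])[0] == pytest.approx(1.0)
        assert spearman_corr(x, [9, 7, 5, 4, 2])[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_vector_flagged_missing(self):
        rho, p = spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_pairwise_deletion(self):
        rho, _ = spearman_corr([1, 2, 3, 4, np.nan], [2, 1, 4, 3, 10])
        assert rho == pytest.approx(0.6)


class TestFisherHypergeom:
    @pytest.mark.parametrize("table,expected", [
        ([[2, 0], [0, 2]], 1 / 3),
        ([[0, 0], [3, 4]], 1.0),
        ([[5, 0], [0, 5]], 2 / 252),
    ])
    def test_fisher_enumeration_values(self, table, expected):
        assert fisher_exact_2x2(table)[1] == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @pytest.mark.parametrize("args,expected", [
        ((5, 5, 5, 20), 1 / 15504),
        ((0, 5, 5, 20), 1.0),
        ((5, 5, 5, 5), 1.0),
    ])
    def test_hypergeom_closed_forms(self, args, expected):
        assert hypergeom_enrich(*args) == pytest.approx(expected)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(6, 5, 5, 20)


class TestSurvival:
    def test_product_limit_hand_example(self):
        curve = km_curve([1, 2, 3], [1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        curve = km_curve([5, 8, 9], [0, 0, 0])
        assert curve.survival_at(100) == 1.0

    def test_single_subject_event(self):
        assert km_curve([4.0], [1]).survival_at(4.0) == 0.0

    def test_curve_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 20)
        events = rng.integers(0, 2, 20)
        a = km_curve(times, events)
        perm = rng.permutation(20)
        b = km_curve(times[perm], events[perm])
        np.testing.assert_allclose(a.survival, b.survival)

    def test_logrank_identical_groups(self):
        res = logrank_test([1, 2, 3], [1, 0, 1], [1, 2, 3], [1, 0, 1])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_logrank_hand_example(self):
        # O-E and hypergeometric variance accumulated per event time by hand
        res = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.statistic == pytest.approx(2.8824, abs=1e-3)
        assert res.p_value == pytest.approx(0.0896, abs=1e-3)

    def test_no_events_warns(self):
        with pytest.warns(DegenerateDataWarning):
            res = logrank_test([1, 2], [0, 0], [3], [0])
        assert res.p_value == 1.0


def test_median_split_ties_to_low_stratum():
    high = median_split([1.0, 2.0, 3.0, 4.0])
    assert list(high) == [False, False, True, True]
    high = median_split([1.0, 2.0, 2.0, 4.0])
    assert list(high) == [False, False, False, True]
    with pytest.raises(ValueError, match="degenerate"):
        median_split([2.0, 2.0, 2.0])


class TestSurvivalCrossCheck:
    """Independent cross-check of the survival primitives against lifelines."""

    def test_km_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(11)
        times = rng.exponential(10, 40).round(2)
        events = rng.integers(0, 2, 40)
        curve = km_curve(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in curve.event_times:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10)

    def test_logrank_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(12)
        for _ in range(5):
            ta = rng.exponential(10, 20)
            tb = rng.exponential(6, 25)
            ea = rng.integers(0, 2, 20)
            eb = rng.integers(0, 2, 25)
            mine = logrank_test(ta, ea, tb, eb)
            theirs = ll_logrank(ta, tb, event_observed_A=ea,
                                event_observed_B=eb)
            assert mine.statistic == pytest.approx(theirs.test_statistic,
                                                   rel=1e-9)
            assert mine.p_value == pytest.approx(theirs.p_value, rel=1e-9)
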