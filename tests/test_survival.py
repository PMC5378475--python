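"""Survival estimator, log-rank test, effect sizes, overlap and t test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from androdyn.errors import DataError, ParameterError
from androdyn.survival import (
    LifespanSummary,
    SurvivalRecord,
    hypergeometric_overlap,
    km_estimate,
    logrank_test,
    mean_lifespan,
    percent_reduction,
    unpaired_t_test,
)


class TestKaplanMeier:
    def test_uncensored_product_limit_by_hand(self, make_records):
        km = km_estimate(make_records([1, 2, 3, 4]))
        assert km.times.tolist() == [1, 2, 3, 4]
        assert km.survival.tolist() == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_single_subject(self, make_records):
        km = km_estimate(make_records([5]))
        assert km.survival_at(5) == 0.0
        assert km.survival_at(4.9) == 1.0

    def test_censoring_by_hand(self, make_records):
        # deaths at 2,2 and 4; censored at 3: S(2)=2/4, S(4)=0
        km = km_estimate(make_records([2, 2, 4], censored=[3]))
        assert km.times.tolist() == [2, 4]
        assert km.survival.tolist() == pytest.approx([0.5, 0.0])
        assert km.at_risk.tolist() == [4, 1]

    def test_death_before_censoring_tie_convention(self, make_records):
        # animal censored on day 2 is still at risk for the day-2 death
        km = km_estimate(make_records([2], censored=[2]))
        assert km.at_risk.tolist() == [2]
        assert km.survival.tolist() == pytest.approx([0.5])

    def test_matches_lifelines_with_censoring(self, rng):
        lifelines = pytest.importorskip("lifelines")
        days = np.ceil(rng.exponential(10, size=80))
        observed = rng.random(80) > 0.25
        recs = [SurvivalRecord(str(i), "g", d, bool(e))
                for i, (d, e) in enumerate(zip(days, observed))]
        km = km_estimate(recs)
        kmf = lifelines.KaplanMeierFitter().fit(days, observed)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(1, 30), min_size=1, max_size=40))
    def test_uncensored_km_is_empirical_survival(self, days):
        recs = [SurvivalRecord(str(i), "g", float(d), True)
                for i, d in enumerate(days)]
        km = km_estimate(recs)
        days_arr = np.array(days, dtype=float)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(days_arr > t))
        # survival is non-increasing, ends at 0 with no censoring
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert km.survival[-1] == pytest.approx(0.0)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(1, 30), min_size=2, max_size=40))
    def test_restricted_mean_equals_arithmetic_mean_uncensored(self, days):
        recs = [SurvivalRecord(str(i), "g", float(d), True)
                for i, d in enumerate(days)]
        assert km_estimate(recs).restricted_mean() == pytest.approx(
            float(np.mean(days)))

    def test_empty_and_mixed_group_inputs_rejected(self, make_records):
        with pytest.raises(DataError):
            km_estimate([])
        mixed = make_records([1], group="a") + make_records([2], group="b")
        with pytest.raises(DataError):
            km_estimate(mixed)


class TestMeanLifespan:
    def test_two_point_mean(self, make_records):
        s = mean_lifespan(make_records([10, 14]))
        assert (s.mean, s.se, s.n) == (12.0, pytest.approx(2.0), 2)

    def test_constant_deaths(self, make_records):
        s = mean_lifespan(make_records([5, 5, 5]))
        assert (s.mean, s.se) == (5.0, 0.0)

    def test_monte_carlo_exponential(self, rng):
        days = rng.exponential(10.0, size=100_000)
        recs = [SurvivalRecord(str(i), "g", float(d), True)
                for i, d in enumerate(days)]
        s = mean_lifespan(recs)
        assert s.mean == pytest.approx(10.0, abs=3 * s.se)

    def test_censored_switches_to_restricted_mean(self, make_records):
        recs = make_records([2, 4, 6], censored=[5])
        s = mean_lifespan(recs)
        assert s.mean == pytest.approx(km_estimate(recs).restricted_mean())
        assert s.n == 4

    def test_all_censored_rejected(self, make_records):
        with pytest.raises(DataError):
            mean_lifespan(make_records([], censored=[3, 4]))


def logrank_two_group_oracle(records):
    """Independent brute-force oracle: explicit 2x2 table at each death day."""
    groups = sorted({r.group for r in records})
    a_days = [(r.day, r.event) for r in records if r.group == groups[0]]
    b_days = [(r.day, r.event) for r in records if r.group == groups[1]]
    death_days = sorted({d for d, e in a_days + b_days if e})
    o_minus_e, var = 0.0, 0.0
    for t in death_days:
        na = sum(1 for d, _ in a_days if d >= t)
        nb = sum(1 for d, _ in b_days if d >= t)
        da = sum(1 for d, e in a_days if e and d == t)
        db = sum(1 for d, e in b_days if e and d == t)
        n, d = na + nb, da + db
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (n - d) / (n - 1) * na * nb / n**2
    chi = o_minus_e**2 / var
    return chi


class TestLogRank:
    def test_identical_groups_null(self, make_records):
        recs = make_records([3, 5, 8], group="a") + \
            make_records([3, 5, 8], group="b")
        res = logrank_test(recs)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_match_table_oracle(self, make_records):
        recs = make_records([1, 2], group="a") + \
            make_records([3, 4], group="b")
        res = logrank_test(recs)
        assert res.chi_square == pytest.approx(logrank_two_group_oracle(recs))
        assert res.df == 1

    def test_label_swap_symmetry(self, make_records, rng):
        days_a = np.ceil(rng.exponential(8, 25))
        days_b = np.ceil(rng.exponential(12, 25))
        recs = [SurvivalRecord(f"a{i}", "a", d, True)
                for i, d in enumerate(days_a)] + \
               [SurvivalRecord(f"b{i}", "b", d, True)
                for i, d in enumerate(days_b)]
        swapped = [SurvivalRecord(r.animal_id, {"a": "b", "b": "a"}[r.group],
                                  r.day, r.event) for r in recs]
        res, res_sw = logrank_test(recs), logrank_test(swapped)
        assert res.chi_square == pytest.approx(res_sw.chi_square)
        assert res.p_value == pytest.approx(res_sw.p_value)

    def test_agrees_with_reference_on_random_datasets(self, rng):
        stats_mod = pytest.importorskip("lifelines.statistics")
        for _ in range(50):
            n = int(rng.integers(10, 60))
            days = np.ceil(rng.exponential(rng.uniform(5, 20), size=n)) + 1
            groups = rng.choice(["a", "b"], size=n)
            censored = rng.random(n) < 0.15
            if len(set(groups[~censored])) < 2:
                continue
            recs = [SurvivalRecord(str(i), g, d, not c)
                    for i, (g, d, c) in enumerate(zip(groups, days, censored))]
            mine = logrank_test(recs)
            ref = stats_mod.multivariate_logrank_test(
                days, groups, event_observed=~censored)
            assert mine.chi_square == pytest.approx(
                ref.test_statistic, rel=1e-7)
            assert mine.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_three_group_statistic_matches_reference(self, rng):
        stats_mod = pytest.importorskip("lifelines.statistics")
        days = np.ceil(rng.exponential(10, 90)) + 1
        groups = np.repeat(["a", "b", "c"], 30)
        recs = [SurvivalRecord(str(i), g, d, True)
                for i, (g, d) in enumerate(zip(groups, days))]
        mine = logrank_test(recs)
        ref = stats_mod.multivariate_logrank_test(days, groups)
        assert mine.df == 2
        assert mine.chi_square == pytest.approx(ref.test_statistic, rel=1e-7)

    def test_single_group_rejected(self, make_records):
        with pytest.raises(DataError):
            logrank_test(make_records([1, 2, 3]))


class TestPercentReduction:
    def test_printed_legend_effect_sizes(self):
        # solitary 12.0 d vs eight grouped 7.7 d; unmated 10.9 vs 6-day-mated 6.8
        assert percent_reduction(12.0, 7.7) == pytest.approx(35.8, abs=0.05)
        assert percent_reduction(10.9, 6.8) == pytest.approx(37.6, abs=0.05)

    def test_identity_and_summary_inputs(self):
        s = LifespanSummary("g", 9.5, 0.3, 40)
        assert percent_reduction(s, s) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(ctrl=st.floats(1.0, 50.0), t1=st.floats(0.1, 50.0),
           t2=st.floats(0.1, 50.0), scale=st.floats(0.1, 10.0))
    def test_antitone_in_treatment_and_scale_invariant(self, ctrl, t1, t2,
                                                       scale):
        lo, hi = sorted((t1, t2))
        assert percent_reduction(ctrl, lo) >= percent_reduction(ctrl, hi)
        assert percent_reduction(ctrl * scale, t1 * scale) == pytest.approx(
            percent_reduction(ctrl, t1), abs=1e-9)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ParameterError):
            percent_reduction(0.0, 5.0)


def overlap_tail_by_enumeration(universe, size_a, size_b, k):
    """Exhaustive oracle: fraction of size_b subsets sharing >= k with a
    fixed size_a set."""
    a = set(range(size_a))
    hits = total = 0
    for b in itertools.combinations(range(universe), size_b):
        hits += len(a & set(b)) >= k
        total += 1
    return hits / total


class TestHypergeometricOverlap:
    def test_zero_overlap_has_tail_one(self):
        assert hypergeometric_overlap(10, 5, 5, 0).p_value == 1.0

    def test_small_universe_enumeration(self):
        res = hypergeometric_overlap(4, 2, 2, 2)
        assert res.p_value == pytest.approx(1 / 6)

    @pytest.mark.parametrize("universe,a,b,k", [
        (8, 3, 4, 2), (10, 5, 5, 3), (12, 6, 4, 1), (12, 7, 7, 5),
        (9, 2, 7, 2), (11, 5, 6, 0),
    ])
    def test_agrees_with_exhaustive_enumeration(self, universe, a, b, k):
        res = hypergeometric_overlap(universe, a, b, k)
        assert res.p_value == pytest.approx(
            overlap_tail_by_enumeration(universe, a, b, k), abs=1e-12)

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ParameterError):
            hypergeometric_overlap(10, 3, 4, 5)


class TestUnpairedT:
    def test_identical_groups(self):
        t, df, p = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 4

    def test_degenerate_variance_conventions(self):
        assert unpaired_t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 2.0, 1.0)
        t, _, p = unpaired_t_test([0.0, 0.0], [1.0, 1.0])
        assert math.isinf(t) and p == 0.0

    def test_welch_differs_under_unequal_variance(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 6, 40)
        _, df_pooled, _ = unpaired_t_test(a, b)
        _, df_welch, _ = unpaired_t_test(a, b, welch=True)
        assert df_pooled == 48
        assert df_welch != df_pooled

    def test_type_one_error_rate_under_null(self, rng):
        reps, n = 1000, 10_000
        rejections = 0
        draws = rng.standard_normal((reps, 2, n))
        for i in range(reps):
            _, _, p = unpaired_t_test(draws[i, 0], draws[i, 1])
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07
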