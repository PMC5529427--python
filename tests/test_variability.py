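"""Capture windows, exact tests, confidence intervals, seasonal machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clptel import (
    AnalysisError,
    MouseOutcome,
    ParameterError,
    best_window,
    binomial_ci,
    capture_table,
    compare_windows,
    fisher_exact_2xk,
    mcnemar_exact,
    sample_size_plan,
    seasonal_analysis,
)
from clptel.variability import round_half_up


def outcomes_from_times(times, censored=0):
    out = [
        MouseOutcome(f"m{i}", float(t), False) for i, t in enumerate(times)
    ]
    out += [MouseOutcome(f"c{j}", None, True) for j in range(censored)]
    return out


class TestCaptureTable:
    def test_fixture_reproduces_percent_column(self, table1_cohort):
        expected = {
            4: 0, 5: 2, 6: 12, 7: 24, 8: 28, 9: 10, 10: 5, 11: 4, 12: 2,
            13: 3, 14: 3, 15: 1, 16: 1, 17: 1, 18: 0, 19: 0, 20: 0, 21: 0,
            22: 1, 23: 2,
        }
        pct = capture_table(table1_cohort).to_percent()["window_pct"]
        for hour, want in expected.items():
            assert pct.loc[hour] == want, f"hour {hour}"

    def test_fixture_denominator_is_uncensored(self, table1_cohort):
        table = capture_table(table1_cohort)
        assert table.n_analyzed == 107
        assert table.data.loc[8, "window_count"] == 30
        assert table.data.loc[8, "window_prop"] == pytest.approx(30 / 107)

    def test_all_at_480_concentrates_in_8h_window(self):
        table = capture_table(outcomes_from_times([480.0] * 107))
        pct = table.to_percent()["window_pct"]
        assert pct.loc[8] == 100
        assert (pct.drop(8) == 0).all()

    def test_cumulative_non_decreasing_and_bounded(self, table1_cohort):
        cum = capture_table(table1_cohort).data["cumulative_prop"]
        assert (cum.diff().dropna() >= 0).all()
        assert cum.iloc[-1] <= 1.0

    def test_state_fractions_partition_unity(self, table1_cohort):
        d = capture_table(table1_cohort).data
        total = d["window_prop"] + d["past_prop"] + d["not_yet_prop"]
        assert np.allclose(total, 1.0)

    def test_each_time_in_exactly_one_window(self):
        # half-open [60h-30, 60h+30) windows partition the axis; boundary
        # times land in the later window only
        table = capture_table(outcomes_from_times([449.9999, 450.0, 509.9999, 510.0]))
        counts = table.data["window_count"]
        assert counts.loc[7] == 1 and counts.loc[8] == 2 and counts.loc[9] == 1
        assert counts.sum() == 4

    def test_all_censored_is_error(self):
        with pytest.raises(AnalysisError):
            capture_table(outcomes_from_times([], censored=5))

    def test_empty_cohort_is_error(self):
        with pytest.raises(AnalysisError):
            capture_table([])


class TestBestWindow:
    def test_fixture_best_is_eight(self, table1_cohort):
        assert best_window(capture_table(table1_cohort)) == 8

    def test_uniform_tie_goes_to_earliest(self):
        times = [h * 60.0 for h in range(4, 25)]
        assert best_window(capture_table(outcomes_from_times(times))) == 4

    def test_single_spike(self):
        assert best_window(capture_table(outcomes_from_times([420.0] * 5))) == 7


class TestSampleSizePlan:
    def test_published_point(self):
        plan = sample_size_plan(120, 0.28)
        assert plan.fold_increase == 3.57
        assert plan.required_total == 429

    def test_identity_at_full_capture(self):
        plan = sample_size_plan(120, 1.0)
        assert plan.fold_increase == 1.0
        assert plan.required_total == 120

    def test_exact_division(self):
        assert sample_size_plan(101, 0.5).required_total == 202

    def test_from_counts_includes_ci(self):
        plan = sample_size_plan(120, successes=30, n=107)
        assert plan.p_hat == pytest.approx(30 / 107)
        assert plan.ci_low == 20

    def test_zero_proportion_rejected(self):
        with pytest.raises(ParameterError):
            sample_size_plan(120, 0.0)


class TestBinomialCI:
    @pytest.mark.parametrize("method", ["wald", "wilson", "clopper-pearson"])
    def test_lower_bound_robustly_20_percent(self, method):
        lo, _ = binomial_ci(30, 107, method=method)
        assert lo == 20

    def test_zero_successes(self):
        lo, _ = binomial_ci(0, 50)
        assert lo == 0

    def test_degenerate_all_successes_wald(self):
        assert binomial_ci(107, 107, method="wald") == (100, 100)

    def test_clopper_pearson_coverage_at_least_nominal(self):
        # exact interval: empirical coverage must not fall below 95% at
        # p = 0.28, n = 107 over 10^4 replicates
        rng = np.random.default_rng(2024)
        x = rng.binomial(107, 0.28, size=10_000)
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(x, 107, alpha=0.05, method="beta")
        coverage = np.mean((lo <= 0.28) & (0.28 <= hi))
        assert coverage >= 0.95

    def test_full_precision_mode(self):
        lo, hi = binomial_ci(30, 107, as_percent=False)
        assert 0.19 < lo < 0.20
        assert 0.36 < hi < 0.37


class TestMcNemarExact:
    def test_published_8h_vs_6h(self):
        assert round_half_up(mcnemar_exact(30, 13), 2) == 0.01

    def test_8h_vs_7h_inferred_counts(self):
        # exact two-sided binomial value, verified against brute-force
        # enumeration; rounds to 0.69
        assert mcnemar_exact(30, 26) == pytest.approx(0.68888, abs=1e-4)

    def test_symmetric_counts_give_one(self):
        assert mcnemar_exact(5, 5) == 1.0

    def test_no_discordance_convention(self):
        assert mcnemar_exact(0, 0) == 1.0

    def test_symmetry_in_arguments(self):
        assert mcnemar_exact(30, 13) == mcnemar_exact(13, 30)

    def test_chi2_variant_close_for_moderate_counts(self):
        assert mcnemar_exact(30, 13, method="chi2cc") == pytest.approx(
            mcnemar_exact(30, 13), abs=0.01
        )

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 16), st.integers(0, 16))
    def test_equals_brute_force_enumeration(self, b, c):
        # enumerate all 2^(b+c) equally likely discordant-pair splits
        n = b + c
        if n > 16:
            return
        m = min(b, c)
        from math import comb

        low = sum(comb(n, k) for k in range(0, m + 1))
        high = sum(comb(n, k) for k in range(n - m, n + 1))
        expected = 1.0 if n == 0 else min(1.0, (low + high) / 2.0 ** n)
        assert mcnemar_exact(b, c) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_statsmodels(self):
        # independent implementation cross-check
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(30, 13), (30, 26), (7, 2), (1, 0)]:
            sm_p = sm_mcnemar([[0, b], [c, 0]], exact=True).pvalue
            assert mcnemar_exact(b, c) == pytest.approx(float(sm_p), rel=1e-9)


class TestFisherExact2xk:
    def test_2x2_matches_hypergeometric_oracle(self):
        from scipy.stats import fisher_exact

        for table in ([[1, 9], [11, 3]], [[5, 1], [2, 7]], [[10, 10], [10, 10]]):
            assert fisher_exact_2xk(table) == pytest.approx(
                fisher_exact(table).pvalue, rel=1e-9
            )

    def test_2x3_matches_reference_value(self):
        # independent oracle: R fisher.test on the same table
        assert fisher_exact_2xk([[5, 2, 7], [3, 6, 4]]) == pytest.approx(
            0.2447986, abs=1e-6
        )

    def test_2x4_matches_reference_value(self):
        assert fisher_exact_2xk([[11, 7, 8, 3], [2, 9, 4, 10]]) == pytest.approx(
            0.0096941, abs=1e-6
        )

    def test_identical_columns_give_one(self):
        assert fisher_exact_2xk([[4, 4], [6, 6]]) == pytest.approx(1.0)

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2xk([[0, 0], [3, 5]]) == 1.0

    def test_too_many_columns_rejected(self):
        with pytest.raises(ParameterError):
            fisher_exact_2xk([[1] * 5, [1] * 5])


def seasonal_cohort(rng, shift_by_season=None, n_per=30):
    seasons = ["winter", "spring", "summer", "fall"]
    shift_by_season = shift_by_season or {}
    out = []
    for s in seasons:
        times = rng.lognormal(np.log(465.0), 0.16, n_per) + shift_by_season.get(s, 0.0)
        times = np.clip(times, 1.0, 1440.0)
        for i, t in enumerate(times):
            out.append(MouseOutcome(f"{s}{i}", float(t), False, season=s))
    return out


class TestSeasonalAnalysis:
    def test_null_cohort_statistics_behave(self):
        rng = np.random.default_rng(5)
        summary = seasonal_analysis(seasonal_cohort(rng), exact_capture_test=False)
        assert summary.kruskal_p > 0.01
        assert set(summary.per_season.index) == {"winter", "spring", "summer", "fall"}
        assert (summary.per_season["n"] == 30).all()

    def test_shifted_season_detected_with_power(self):
        # +120 min in one season, n = 30/season: Kruskal-Wallis should
        # reject at alpha = .05 in at least 80% of 500 replicates
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(500):
            cohort = seasonal_cohort(rng, shift_by_season={"winter": 120.0})
            s = seasonal_analysis(cohort, exact_capture_test=False)
            rejections += s.kruskal_p < 0.05
        assert rejections / 500 >= 0.80

    def test_monotone_ambient_temperature_gives_perfect_spearman(self):
        out = [
            MouseOutcome(f"m{i}", 300.0 + 10 * i, False,
                         season=["winter", "spring"][i % 2],
                         ambient_temp=19.0 + 0.5 * i)
            for i in range(20)
        ]
        s = seasonal_analysis(out, exact_capture_test=False)
        assert s.spearman_r == pytest.approx(1.0)

    def test_capture_fisher_on_small_groups(self):
        rng = np.random.default_rng(11)
        s = seasonal_analysis(seasonal_cohort(rng, n_per=12))
        assert s.capture_fisher_p is not None
        assert 0.0 <= s.capture_fisher_p <= 1.0

    def test_insufficient_seasons_rejected(self):
        out = [MouseOutcome("a", 400.0, False, season="winter"),
               MouseOutcome("b", 410.0, False, season="winter")]
        with pytest.raises(AnalysisError):
            seasonal_analysis(out)


class TestCompareWindows:
    def test_fixture_8_vs_6(self, table1_cohort):
        cmp = compare_windows(capture_table(table1_cohort), 8, 6)
        assert (cmp.count_a, cmp.count_b) == (30, 13)
        assert round_half_up(cmp.p_value, 2) == 0.01

    def test_fixture_8_vs_9_strongly_significant(self, table1_cohort):
        cmp = compare_windows(capture_table(table1_cohort), 8, 9)
        assert cmp.p_value < 0.01

    def test_symmetric(self, table1_cohort):
        table = capture_table(table1_cohort)
        assert compare_windows(table, 8, 6).p_value == compare_windows(table, 6, 8).p_value
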