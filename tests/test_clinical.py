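import numpy as np
import pytest

from kinact import (
    contingency_test,
    kaplan_meier,
    logrank_and_hr,
    response_rates,
)
from oracles import fisher_two_sided


class TestResponseRates:
    def test_trial_worked_example(self):
        """PR 15, SD 1, PD 1, NE 2 of 19: ORR 15/17 = 88.24%, DCR 16/17 = 94.12%."""
        responses = ["PR"] * 15 + ["SD"] + ["PD"] + ["NE"] * 2
        summary = response_rates(responses)
        assert summary.n_total == 19 and summary.n_evaluable == 17
        assert round(summary.orr_percent, 2) == 88.24
        assert round(summary.dcr_percent, 2) == 94.12

    def test_simple_arithmetic(self):
        summary = response_rates(["CR", "CR", "SD", "PD"])
        assert round(summary.orr_percent, 2) == 50.00
        assert round(summary.dcr_percent, 2) == 75.00

    def test_all_ne_gives_undefined_rates(self):
        summary = response_rates(["NE", "NE"])
        assert summary.orr_percent is None and summary.dcr_percent is None

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="allowed"):
            response_rates(["PR", "WHAT"])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = kaplan_meier([1, 2, 3, 4], [True] * 4)
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2.0

    def test_all_censored_curve_stays_at_one(self):
        km = kaplan_meier([3, 5, 8], [False] * 3)
        assert len(km.event_times) == 0
        assert km.median is None
        assert km.survival_at(100.0) == 1.0

    def test_product_limit_hand_example(self):
        """Times 5+, 8, 12, 16+: S(8) = 2/3, S(12) = 1/3."""
        km = kaplan_meier([5, 8, 12, 16], [False, True, True, False])
        assert km.survival_at(8) == pytest.approx(2 / 3)
        assert km.survival_at(12) == pytest.approx(1 / 3)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=40)
        e = rng.random(40) < 0.7
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tt, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(float(kmf.predict(tt)), abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0], [True])


class TestLogRank:
    def test_identical_groups_null(self):
        g = ([1, 2, 3, 4, 5], [True] * 5)
        res = logrank_and_hr(g, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.hazard_ratio == pytest.approx(1.0)

    def test_hand_tabulated_oe(self):
        """Group 1 dies at 1, 2; group 2 at 3, 4.  Hand tabulation over the
        risk sets: E1 = 2/4 + 1/3 = 5/6 (then 0), E2 = 4 - 5/6 = 19/6,
        V = 1/4 + 2/9 (later tables have an empty group or n = 1)."""
        res = logrank_and_hr(([1, 2], [True, True]), ([3, 4], [True, True]))
        assert res.observed[0] == pytest.approx(2.0)
        assert res.expected[0] == pytest.approx(5 / 6)
        v = 1 / 4 + 2 / 9
        assert res.chi_square == pytest.approx((2 - 5 / 6) ** 2 / v)
        assert res.hazard_ratio == pytest.approx((2 / (5 / 6)) / (2 / (19 / 6)))

    def test_matches_lifelines_statistic(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(1)
        t1, t2 = rng.exponential(10, 30), rng.exponential(18, 25)
        e1 = rng.random(30) < 0.8
        e2 = rng.random(25) < 0.8
        res = logrank_and_hr((t1, e1), (t2, e2))
        ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert res.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_hazard_ratio_parameter_recovery(self):
        """Exponential groups with true HR 0.5: mean MH estimate within 10%."""
        rng = np.random.default_rng(2)
        estimates = []
        for _ in range(200):
            t1 = rng.exponential(2.0, 120)  # hazard 0.5
            t2 = rng.exponential(1.0, 120)  # hazard 1.0
            res = logrank_and_hr((t1, [True] * 120), (t2, [True] * 120))
            estimates.append(res.hazard_ratio)
        assert np.mean(estimates) == pytest.approx(0.5, rel=0.10)

    def test_zero_events_leaves_hr_undefined(self):
        with pytest.warns(UserWarning, match="zero events"):
            res = logrank_and_hr(([1, 2], [False, False]), ([1, 2], [True, True]))
        assert res.hazard_ratio is None
        assert np.isfinite(res.chi_square)

    def test_ci_brackets_hr(self):
        rng = np.random.default_rng(3)
        res = logrank_and_hr(
            (rng.exponential(5, 40), [True] * 40), (rng.exponential(9, 40), [True] * 40)
        )
        assert res.ci_low < res.hazard_ratio < res.ci_high


class TestContingency:
    def test_fisher_hand_enumeration(self):
        _, p = contingency_test([[3, 1], [1, 3]], method="fisher")
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_chi2_balanced_table(self):
        stat, p = contingency_test([[10, 10], [10, 10]], method="chi2")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        stat, p = contingency_test([[0, 5], [0, 7]])
        assert stat is None and p == 1.0

    def test_auto_picks_fisher_on_small_expected(self):
        _, p_auto = contingency_test([[3, 1], [1, 3]], method="auto")
        _, p_fisher = contingency_test([[3, 1], [1, 3]], method="fisher")
        assert p_auto == p_fisher

    @pytest.mark.parametrize("seed", range(10))
    def test_fisher_matches_exact_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        _, p = contingency_test([[a, b], [c, d]], method="fisher")
        assert p == pytest.approx(float(fisher_two_sided(a, b, c, d)), abs=1e-9)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            contingency_test([[1.5, 2], [3, 4]])
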