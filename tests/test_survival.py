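import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy.optimize import minimize_scalar

from hemodose import (
    adjust_pvalues,
    cox_fit,
    cox_score_test,
    kaplan_meier,
    ph_check,
    quartile_logrank,
)
from hemodose.synthetic import CohortSpec, simulate_cohort


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self):
        curve = kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert curve.at(0.0) == 1.0
        assert curve.at(2.5) == 0.5

    def test_single_censored_observation(self):
        curve = kaplan_meier([5.0], [0])
        assert curve.all_censored
        assert curve.at(10.0) == 1.0

    def test_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2: S(1) = 2/3; at t=3 the risk set
        # is the single remaining patient, so S(3) = 2/3 * (1 - 1/1) = 0
        curve = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.at(1.0) == pytest.approx(2 / 3)
        assert curve.at(3.0) == 0.0
        # a later censoring keeps the last factor < 1: S(3) = 1/3
        curve = kaplan_meier([1.0, 3.0, 4.0], [1, 1, 0])
        assert curve.at(3.0) == pytest.approx(1 / 3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])
        with pytest.raises(ValueError):
            kaplan_meier([0.0], [1])
        with pytest.raises(ValueError):
            kaplan_meier([1.0], [2])


def manual_logrank(times_a, events_a, times_b, events_b):
    """Hand-rolled observed-minus-expected hypergeometric log-rank chi^2."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a), np.asarray(events_b)
    all_times = np.unique(np.concatenate([times_a[events_a == 1], times_b[events_b == 1]]))
    observed_minus_expected = 0.0
    variance = 0.0
    for t in all_times:
        n_a = np.sum(times_a >= t)
        n_b = np.sum(times_b >= t)
        d_a = np.sum((times_a == t) & (events_a == 1))
        d_b = np.sum((times_b == t) & (events_b == 1))
        n, d = n_a + n_b, d_a + d_b
        observed_minus_expected += d_a - d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return observed_minus_expected**2 / variance


class TestQuartileLogrank:
    def test_identical_groups_give_null_statistic(self):
        # bottom quartile = the two 1s, top quartile = the two 10s; both
        # extreme groups carry the identical event-time multiset {3, 5}
        values = np.array([1, 1, 5, 5, 6, 6, 10, 10], dtype=float)
        times = np.array([3.0, 5.0, 4.0, 6.0, 4.0, 6.0, 3.0, 5.0])
        events = np.ones(8, dtype=int)
        statistic, p = quartile_logrank(values, times, events)
        assert statistic == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_manual_hypergeometric_sum(self):
        rng = np.random.default_rng(4)
        values = np.arange(8, dtype=float)
        times = rng.exponential(10.0, size=8).round(1) + 0.1
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        statistic, _ = quartile_logrank(values, times, events)
        low = values <= np.quantile(values, 0.25)
        high = values >= np.quantile(values, 0.75)
        expected = manual_logrank(times[low], events[low], times[high], events[high])
        assert statistic == pytest.approx(expected, rel=1e-10)

    def test_null_calibration(self):
        """Rejection rate at alpha=0.05 is ~5% when metric is independent."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_replicates = 400
        for _ in range(n_replicates):
            values = rng.normal(size=40)
            times = rng.exponential(100.0, size=40)
            events = np.ones(40, dtype=int)
            _, p = quartile_logrank(values, times, events)
            rejections += p < 0.05
        assert rejections / n_replicates == pytest.approx(0.05, abs=0.03)

    def test_degenerate_and_small_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            quartile_logrank([1.0] * 7, [1.0] * 7, [1] * 7)
        with pytest.raises(ValueError, match="degenerate"):
            quartile_logrank([2.0] * 10, np.arange(1.0, 11.0), [1] * 10)


class TestCoxFit:
    def toy_frame(self):
        return pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 0, 1, 1],
                "x": [1.0, 1.0, 0.0, 1.0, 0.0, 0.0],
            }
        )

    def test_coefficient_matches_brute_force_partial_likelihood(self):
        frame = self.toy_frame()
        times = frame["time"].to_numpy()
        events = frame["event"].to_numpy()
        x = frame["x"].to_numpy()

        def negative_log_partial_likelihood(beta):
            total = 0.0
            for i in range(len(times)):
                if events[i]:
                    risk = times >= times[i]
                    total += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -total

        brute = minimize_scalar(
            negative_log_partial_likelihood, bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        ).x
        fit = cox_fit(frame, "time", "event", ["x"])
        assert fit.converged
        assert fit.summary.loc["x", "coef"] == pytest.approx(brute, abs=1e-4)
        assert fit.summary.loc["x", "hr"] == pytest.approx(np.exp(brute), rel=1e-4)

    def test_score_test_equals_logrank_statistic(self):
        frame = self.toy_frame()
        fit = cox_fit(frame, "time", "event", ["x"])
        grouped = frame.groupby("x")
        a, b = (grouped.get_group(level) for level in (1.0, 0.0))
        reference = logrank_test(a["time"], b["time"], a["event"], b["event"])
        assert fit.score_test == pytest.approx(reference.test_statistic, abs=1e-6)

    def test_constant_covariate_reported_as_null_effect(self):
        frame = self.toy_frame()
        frame["flat"] = 0.0
        fit = cox_fit(frame, "time", "event", ["x", "flat"])
        assert fit.summary.loc["flat", "coef"] == 0.0
        assert fit.summary.loc["flat", "hr"] == 1.0
        assert "flat" in fit.dropped_terms

    def test_dummy_coding_of_categoricals(self):
        rng = np.random.default_rng(5)
        n = 120
        frame = pd.DataFrame(
            {
                "time": rng.exponential(100.0, n),
                "event": rng.integers(0, 2, n),
                "grade": rng.choice(["low", "mid", "high"], n),
            }
        )
        fit = cox_fit(frame, "time", "event", ["grade"], categorical=["grade"])
        assert len(fit.summary) == 2  # three levels, first dropped
        assert all(term.startswith("grade_") for term in fit.summary.index)

    def test_complete_case_exclusion_counted(self):
        frame = self.toy_frame()
        frame.loc[0, "x"] = np.nan
        fit = cox_fit(frame, "time", "event", ["x"])
        assert fit.n_excluded == 1
        assert fit.n_used == 5

    def test_too_few_events_rejected(self):
        frame = self.toy_frame()
        frame["event"] = [1, 0, 0, 0, 0, 0]
        with pytest.raises(ValueError, match="at least 2 events"):
            cox_fit(frame, "time", "event", ["x"])

    def test_parameter_recovery_single_cohort(self):
        """Estimate close to truth and inside its own CI on one big cohort."""
        table, truth = simulate_cohort(
            CohortSpec(n_patients=800, dose_mode="surrogate", seed=17)
        )
        fit = cox_fit(table, "time_os", "event_os", ["d90_blood"])
        beta = truth["betas"]["d90_blood"]
        row = fit.summary.loc["d90_blood"]
        assert row["coef"] == pytest.approx(beta, abs=0.1)
        assert np.log(row["ci_lower"]) < beta < np.log(row["ci_upper"])


class TestPhCheck:
    def test_calibrated_under_proportional_hazards(self):
        rng = np.random.default_rng(7)
        p_values = []
        for _ in range(60):
            n = 100
            x = rng.normal(size=n)
            times = rng.exponential(np.exp(-0.3 * x))
            frame = pd.DataFrame({"time": times, "event": 1, "x": x})
            fit = cox_fit(frame, "time", "event", ["x"])
            p_values.append(ph_check(fit)["x"])
        assert np.mean(np.asarray(p_values) < 0.05) < 0.2

    def test_detects_constructed_violation(self):
        # crossing hazards: effect reverses over time
        rng = np.random.default_rng(8)
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        early = rng.exponential(0.5, n)
        late = 2.0 + rng.exponential(0.5, n)
        times = np.where(x == 1, early, late)
        frame = pd.DataFrame({"time": times, "event": 1, "x": x})
        fit = cox_fit(frame, "time", "event", ["x"])
        assert ph_check(fit)["x"] < 0.01

    def test_not_applicable_with_too_few_events(self):
        frame = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 0, 0], "x": [0.0, 1.0, 0.0, 1.0]}
        )
        fit = cox_fit(frame, "time", "event", ["x"])
        assert np.isnan(ph_check(fit, min_events=3)["x"])


class TestAdjustPvalues:
    def test_single_test_unchanged(self):
        for method in ("bonferroni", "holm", "bh"):
            np.testing.assert_allclose(adjust_pvalues([0.01], method), [0.01])

    def test_bonferroni_multiplies(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.04], "bonferroni"), [0.02, 0.08]
        )

    def test_bh_matches_step_up_hand_calculation(self):
        # sorted p (0.01, 0.02, 0.03, 0.04), m=4:
        # raw m/i * p = (0.04, 0.04, 0.04, 0.04) after monotone step-up
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04, 0.04, 0.04, 0.04]
        )

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.0, 1.0, size=25)
        assert np.all(adjust_pvalues(p, "holm") <= adjust_pvalues(p, "bonferroni") + 1e-15)

    def test_clipping_and_validation(self):
        assert adjust_pvalues([0.9, 0.95], "bonferroni").max() == 1.0
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "holm")
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "sidak")
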