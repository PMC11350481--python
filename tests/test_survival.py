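"""Kaplan-Meier, log-rank, and Cox fits vs hand/enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from sslineage.surv import (
    SurvivalRecord,
    cox_fit,
    km_fit,
    km_point_estimate,
    logrank_test,
    records_to_frame,
)

from . import oracles


def frame(times, events, **cols):
    df = pd.DataFrame({"time": times, "event": events})
    for k, v in cols.items():
        df[k] = v
    return df


class TestSurvivalRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            SurvivalRecord("s", 0.0, 1)
        with pytest.raises(ValueError):
            SurvivalRecord("s", 1.0, 2)
        df = records_to_frame([SurvivalRecord("s1", 12.0, 1, "TCI")])
        assert df.loc["s1", "time"] == 12.0


class TestKmFit:
    def test_one_death_of_four(self):
        fit = km_fit(frame([1.0, 5.0, 6.0, 7.0], [1, 0, 0, 0]))
        assert fit.predict(1.0) == pytest.approx(0.75)
        assert fit.predict(0.5) == 1.0

    def test_no_events_s_is_one(self):
        fit = km_fit(frame([1.0, 2.0, 3.0], [0, 0, 0]))
        assert fit.predict(3.0) == 1.0

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        times = np.sort(rng.exponential(10, size=25))
        fit = km_fit(frame(times, np.ones(25, dtype=int)))
        for t in times:
            ecdf = np.mean(times <= t)
            assert fit.predict(t) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_matches_hand_product_limit_with_censoring(self, rng):
        times = rng.exponential(10, size=40).round(2) + 0.01
        events = rng.integers(0, 2, size=40)
        fit = km_fit(frame(times, events))
        for t, s, var in oracles.km_by_hand(times.tolist(), events.tolist()):
            assert fit.predict(t) == pytest.approx(s, abs=1e-12)
            assert fit.greenwood_variance(t) == pytest.approx(var, rel=1e-9)


class TestKmPointEstimate:
    def test_no_events_before_t0(self):
        fit = km_fit(frame([40.0, 50.0, 60.0], [0, 0, 1]))
        est, lo, hi, beyond = km_point_estimate(fit, 36.0)
        assert (est, hi) == (1.0, 1.0)
        assert not beyond

    def test_hand_greenwood_cloglog_ci(self):
        fit = km_fit(frame([1.0, 5.0, 6.0, 7.0], [1, 0, 0, 0]))
        est, lo, hi, _ = km_point_estimate(fit, 3.0)
        s = 0.75
        cum = 1 / (4 * 3)
        se = math.sqrt(cum) / abs(math.log(s))
        z = 1.959963984540054
        assert est == pytest.approx(s)
        assert lo == pytest.approx(s ** math.exp(z * se), rel=1e-9)
        assert hi == pytest.approx(s ** math.exp(-z * se), rel=1e-9)
        assert lo <= est <= hi

    def test_single_subject_event_before_t0(self):
        fit = km_fit(frame([10.0], [1]))
        est, *_ = km_point_estimate(fit, 36.0)
        assert est == 0.0

    def test_beyond_followup_flagged(self):
        fit = km_fit(frame([10.0, 20.0], [1, 0]))
        with pytest.warns(UserWarning, match="follow-up"):
            *_, beyond = km_point_estimate(fit, 100.0)
        assert beyond


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        df = frame([1.0, 2.0, 3.0] * 2, [1, 1, 0] * 2,
                   g=["A"] * 3 + ["B"] * 3)
        chi2, p = logrank_test(df, "g")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_matches_hand_oe_table(self):
        df = frame([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], g=["A", "A", "B", "B"])
        chi2, _p = logrank_test(df, "g")
        want = oracles.logrank_by_hand([1.0, 2.0], [1, 1], [3.0, 4.0], [1, 1])
        assert chi2 == pytest.approx(want, rel=1e-9)

    def test_symmetric_under_relabeling_and_time_rescale(self, rng):
        times = rng.exponential(10, size=30)
        events = rng.integers(0, 2, size=30)
        g = np.where(rng.random(30) < 0.5, "A", "B")
        if len(set(g)) < 2:
            g[0] = "A" if g[1] == "B" else "B"
        df = frame(times, events, g=g)
        chi2_a, _ = logrank_test(df, "g")
        df2 = frame(times * 7.3, events, g=np.where(g == "A", "B", "A"))
        chi2_b, _ = logrank_test(df2, "g")
        assert chi2_a == pytest.approx(chi2_b, rel=1e-9)

    def test_power_against_planted_hazard_ratio(self):
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 200
        for _ in range(reps):
            t_a = rng.exponential(1.0, size=60)
            t_b = rng.exponential(1.0 / 2.5, size=60)
            df = frame(np.concatenate([t_a, t_b]), np.ones(120, dtype=int),
                       g=["A"] * 60 + ["B"] * 60)
            _, p = logrank_test(df, "g")
            rejections += p < 0.05
        assert rejections / reps >= 0.80

    def test_single_group_rejected(self):
        df = frame([1.0, 2.0], [1, 1], g=["A", "A"])
        with pytest.raises(ValueError):
            logrank_test(df, "g")


class TestCoxFit:
    def test_tiny_dataset_matches_partial_likelihood_grid_search(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 0]
        x = [1.0, 0.0, 1.0, 0.0]
        df = frame(times, events, x=x)
        fit = cox_fit(df, ["x"])
        want = oracles.cox_grid_search(times, events, x)
        assert fit.coef["x"] == pytest.approx(want, abs=1e-5)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(11)
        betas = []
        for _ in range(100):
            n = 500
            x = rng.integers(0, 2, size=n).astype(float)
            t = rng.exponential(10, size=n)
            c = rng.uniform(5, 30, size=n)
            df = frame(np.minimum(t, c), (t <= c).astype(int), x=x)
            betas.append(cox_fit(df, ["x"]).coef["x"])
        assert abs(np.mean(betas)) < 0.1

    def test_flipped_covariate_gives_reciprocal_hr(self, rng):
        n = 80
        x = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(10 / (1 + x), size=n)
        df = frame(t, np.ones(n, dtype=int), x=x)
        hr = cox_fit(df, ["x"]).hr["x"]
        df2 = frame(t, np.ones(n, dtype=int), x=1 - x)
        assert cox_fit(df2, ["x"]).hr["x"] == pytest.approx(1 / hr, rel=1e-6)

    def test_time_shift_invariance(self, rng):
        n = 60
        x = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(10, size=n)
        e = rng.integers(0, 2, size=n)
        if e.sum() == 0:
            e[0] = 1
        b1 = cox_fit(frame(t, e, x=x), ["x"]).coef["x"]
        b2 = cox_fit(frame(t + 100.0, e, x=x), ["x"]).coef["x"]
        assert b1 == pytest.approx(b2, abs=1e-8)

    def test_ci_contains_hr(self, rng):
        n = 100
        x = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(10 / (1 + x), size=n)
        fit = cox_fit(frame(t, np.ones(n, dtype=int), x=x), ["x"])
        assert fit.ci_low["x"] < fit.hr["x"] < fit.ci_high["x"]
        assert fit.hr["x"] > 0

    def test_interaction_column_is_product(self, rng):
        n = 120
        a = rng.integers(0, 2, size=n).astype(float)
        b = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(10, size=n)
        df = frame(t, np.ones(n, dtype=int), a=a, b=b)
        fit = cox_fit(df, ["a", "b"], include_interaction=True)
        assert "a*b" in fit.coef.index

    def test_rank_deficient_design_rejected(self, rng):
        n = 30
        x = rng.integers(0, 2, size=n).astype(float)
        df = frame(rng.exponential(10, size=n), np.ones(n, dtype=int),
                   a=x, b=x)
        with pytest.raises(ValueError, match="rank"):
            cox_fit(df, ["a", "b"])

    def test_no_events_rejected(self):
        df = frame([1.0, 2.0], [0, 0], x=[0.0, 1.0])
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])

    def test_recovers_planted_log_hazard(self):
        """Mean beta-hat near log 2.5 for NI-within-ADRN style simulation."""
        rng = np.random.default_rng(17)
        beta_true = math.log(2.5)
        betas = []
        for _ in range(60):
            n = 240  # 120 per arm
            x = np.repeat([0.0, 1.0], n // 2)
            lam = (math.log(2) / 60.0) * np.exp(beta_true * x)
            t = rng.exponential(1 / lam)
            c = rng.uniform(24, 120, size=n)
            df = frame(np.minimum(t, c), (t <= c).astype(int), x=x)
            betas.append(cox_fit(df, ["x"]).coef["x"])
        assert abs(np.mean(betas) - beta_true) < 0.25
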