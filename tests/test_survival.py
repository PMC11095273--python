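import numpy as np
import pandas as pd
import pytest

from catlet.errors import ValidationError
from catlet.survival import (
    assign_tertiles,
    cox_effect,
    km_estimate,
    logrank_test,
    trend_test,
)


class TestTertiles:
    def test_published_bounds_classify_boundary_scores(self):
        out = assign_tertiles([12, 13, 19], explicit_bounds=(12, 18))
        assert list(out.labels) == ["low", "mid", "top"]

    def test_empirical_tertiles_on_three_distinct_scores(self):
        out = assign_tertiles([1.0, 2.0, 3.0])
        assert sorted(out.labels) == ["low", "mid", "top"]

    def test_degenerate_scores_warn_and_collapse(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = assign_tertiles([5.0] * 10)
        assert set(out.labels) == {"low"}

    def test_unordered_bounds_rejected(self):
        with pytest.raises(ValidationError, match="ordered"):
            assign_tertiles([1, 2, 3], explicit_bounds=(18, 12))


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([4, 4, 4], [False, False, False])
        assert np.allclose(curve["survival"], 1.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(2.0, size=200)
        curve = km_estimate(times, np.ones(200, dtype=bool))
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_hand_product_limit_two_patients(self):
        # one event at t=1 of two at risk: S(1) = 1 - 1/2
        curve = km_estimate([1.0, 4.0], [True, False]).set_index("time")
        assert curve.loc[1.0, "survival"] == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        g = ([1.0, 2.0, 3.0, 4.0], [True, True, False, False])
        chi2, df, p = logrank_test([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_fully_separated_event_times_are_significant(self):
        early = ([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], [True] * 6)
        late = ([3.0, 3.2, 3.4, 3.6, 3.8, 4.0], [True] * 6)
        chi2, _, p = logrank_test([early, late])
        assert p < 0.001
        assert chi2 > 10

    def test_two_group_label_permutation_invariance(self, rng):
        a = (rng.exponential(1, 30), rng.random(30) < 0.7)
        b = (rng.exponential(2, 25), rng.random(25) < 0.7)
        stat_ab = logrank_test([a, b])[0]
        stat_ba = logrank_test([b, a])[0]
        assert stat_ab == pytest.approx(stat_ba, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([([1.0], [True])])


class TestTrend:
    def test_equal_rates_null(self):
        z, p = trend_test([10, 10, 10], [50, 50, 50])
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_monotone_rates_positive_direction(self):
        z, _ = trend_test([2, 10, 25], [50, 50, 50])
        assert z > 0

    def test_hand_computed_example(self):
        # events 5/50, 10/50, 20/50 with scores (1,2,3):
        # p = 35/150, numerator = 85 - p*300 = 15,
        # variance = p(1-p) * 100 = 17.888..., z = 15/sqrt(17.888...)
        z, p = trend_test([5, 10, 20], [50, 50, 50])
        assert z == pytest.approx(15.0 / np.sqrt((35 / 150) * (115 / 150) * 100))
        assert p < 0.01

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            trend_test([1, 2], [10, 0])


def _sim_cox_frame(rng, n, log_hr, sd=1.0):
    x = rng.normal(0, sd, n)
    lam = 0.1 * np.exp(log_hr * x / sd)
    t_event = rng.exponential(1 / lam)
    time = np.minimum(t_event, 4.0)
    return pd.DataFrame(
        {"time": np.maximum(time, 1e-9), "event": (t_event <= 4.0).astype(int), "x": x}
    )


class TestCox:
    def test_independent_predictor_gives_null_hr(self, rng):
        df = _sim_cox_frame(rng, 4000, log_hr=0.0)
        est = cox_effect(df, "x", scale="per_sd")[0]
        assert est.ci_low < 1.0 < est.ci_high
        assert est.hazard_ratio == pytest.approx(1.0, abs=0.1)

    def test_recovers_generating_hazard_ratio(self, rng):
        df = _sim_cox_frame(rng, 3000, log_hr=np.log(1.9))
        est = cox_effect(df, "x", scale="per_sd")[0]
        assert est.ci_low < 1.9 < est.ci_high

    def test_doubling_sd_halves_log_hr(self, rng):
        df = _sim_cox_frame(rng, 1000, log_hr=np.log(2.0))
        est1 = cox_effect(df, "x", scale="per_sd", sd=1.0)[0]
        est2 = cox_effect(df, "x", scale="per_sd", sd=2.0)[0]
        assert np.log(est2.hazard_ratio) == pytest.approx(
            2 * np.log(est1.hazard_ratio), rel=1e-6
        )

    def test_tertile_scale_reports_mid_and_top_vs_low(self, rng):
        df = _sim_cox_frame(rng, 900, log_hr=np.log(2.0))
        from catlet.survival import assign_tertiles

        df["tert"] = assign_tertiles(df["x"].to_numpy()).labels
        ests = cox_effect(df, "tert", scale="tertile_vs_low")
        assert [e.term for e in ests] == ["tertile_mid", "tertile_top"]
        assert ests[1].hazard_ratio > ests[0].hazard_ratio > 0.5

    def test_zero_variance_predictor_rejected(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 0, 1, 0], "x": [1.0] * 4})
        with pytest.raises(ValidationError, match="variance"):
            cox_effect(df, "x", scale="per_sd")

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"time": [1, 2], "event": [1, 0], "x": [1.0, np.nan]})
        with pytest.raises(ValidationError, match="missing"):
            cox_effect(df, "x")
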