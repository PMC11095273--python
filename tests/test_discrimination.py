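import numpy as np
import pytest

from catlet.discrimination import (
    auc,
    binary_outcome_at_horizon,
    compare_auc_paired,
    cv_auc,
    fit_risk_model,
)
from catlet.errors import ValidationError


def brute_force_auc(predictions, outcomes):
    """Proportion of concordant event/non-event pairs, half credit for ties."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    pos, neg = p[y], p[~y]
    wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestRiskModel:
    def test_predictions_monotone_and_calibrated_in_the_large(self, rng):
        x = rng.normal(size=500)
        y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(int)
        preds, _ = fit_risk_model(x, y)
        order = np.argsort(x)
        assert np.all(np.diff(preds[order]) >= -1e-12)
        assert preds.mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_uncorrelated_score_predicts_event_rate(self, rng):
        x = rng.normal(size=2000)
        y = (rng.random(2000) < 0.3).astype(int)
        preds, _ = fit_risk_model(x, y)
        assert np.allclose(preds, y.mean(), atol=0.1)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            fit_risk_model([1.0, 2.0, 3.0], [1, 1, 1])


class TestHorizonLabels:
    def test_censored_before_horizon_excluded(self):
        keep, labels, n_excl = binary_outcome_at_horizon(
            times=[0.5, 2.0, 4.0, 3.0], events=[True, False, False, True], horizon=4.0
        )
        assert n_excl == 1                      # censored event-free at 2y
        assert list(labels) == [1, 0, 1]

    def test_sensitivity_mode_keeps_all(self):
        keep, labels, n_excl = binary_outcome_at_horizon(
            [0.5, 2.0], [True, False], censored_as_nonevent=True
        )
        assert n_excl == 0
        assert list(labels) == [1, 0]


class TestAuc:
    def test_perfect_constant_and_hand_example(self):
        y = [1, 1, 0, 0]
        assert auc([0.9, 0.8, 0.7, 0.1], y).auc == pytest.approx(1.0)
        assert auc([0.5] * 4, y).auc == pytest.approx(0.5)
        assert auc([0.9, 0.2, 0.8, 0.1], y).auc == pytest.approx(0.75)

    def test_rank_formula_matches_brute_force_pair_counting(self, rng):
        for _ in range(100):
            n = rng.integers(4, 51)
            y = np.zeros(n, dtype=int)
            y[: rng.integers(1, n)] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            p = rng.choice(np.round(np.linspace(0, 1, 11), 2), size=n)  # force ties
            assert auc(p, y).auc == pytest.approx(brute_force_auc(p, y), abs=1e-12)

    def test_requires_both_classes(self):
        with pytest.raises(ValidationError):
            auc([0.1, 0.2], [1, 1])

    def test_delong_variance_shrinks_with_replication(self, rng):
        y = np.array([1] * 20 + [0] * 30)
        p = rng.random(50)
        ci = auc(p, y)
        ci_rep = auc(np.tile(p, 4), np.tile(y, 4))
        width = ci.ci_high - ci.ci_low
        width_rep = ci_rep.ci_high - ci_rep.ci_low
        assert width_rep == pytest.approx(width / 2, rel=0.05)


class TestPairedComparison:
    def test_identical_models_no_difference(self, rng):
        p = rng.random(100)
        y = (rng.random(100) < 0.3).astype(int)
        res = compare_auc_paired(p, p, y)
        assert res["difference"] == 0.0
        assert res["p_value"] == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.random(200), rng.random(200)
        y = (rng.random(200) < 0.4).astype(int)
        r1 = compare_auc_paired(a, b, y)
        r2 = compare_auc_paired(b, a, y)
        assert r1["difference"] == pytest.approx(-r2["difference"])
        assert r1["p_value"] == pytest.approx(r2["p_value"])

    def test_detects_added_informative_signal(self):
        # power check: nested models with genuinely informative added signal
        from catlet.synthetic import PairedPredictionConfig, generate_paired_predictions

        rejections = 0
        reps = 200
        for seed in range(reps):
            po, pn, y, _ = generate_paired_predictions(
                PairedPredictionConfig(n=1000, seed=seed)
            )
            if compare_auc_paired(pn, po, y)["p_value"] < 0.05:
                rejections += 1
        assert rejections / reps > 0.5  # well above the 5% null level

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            compare_auc_paired([0.1], [0.1, 0.2], [1, 0])


class TestCrossValidation:
    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=300)
        y = (rng.random(300) < 0.3).astype(int)
        r1 = cv_auc(x, y, k=10, seed=11)
        r2 = cv_auc(x, y, k=10, seed=11)
        assert r1 == r2

    def test_null_signal_near_half(self, rng):
        x = rng.normal(size=2000)
        y = (rng.random(2000) < 0.25).astype(int)
        assert cv_auc(x, y, k=10, seed=0).cv_auc == pytest.approx(0.5, abs=0.06)

    def test_cv_auc_not_optimistic_on_average(self):
        # out-of-fold AUC should not exceed apparent AUC on average
        rng = np.random.default_rng(5)
        gaps = []
        for _ in range(200):
            x = rng.normal(size=120)
            y = (rng.random(120) < 1 / (1 + np.exp(-0.5 * x))).astype(int)
            if y.sum() < 5 or y.sum() > 115:
                continue
            preds, _ = fit_risk_model(x, y)
            apparent = auc(preds, y).auc
            cv = cv_auc(x, y, k=5, seed=1).cv_auc
            gaps.append(apparent - cv)
        assert np.mean(gaps) > 0

    def test_fold_reduction_warns_when_events_scarce(self, rng):
        x = rng.normal(size=40)
        y = np.array([1, 1, 1] + [0] * 37)
        with pytest.warns(UserWarning, match="reducing folds"):
            cv_auc(x, y, k=10, seed=0)
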