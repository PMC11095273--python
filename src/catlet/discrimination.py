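"""Discrimination of risk scores: logistic risk models, ROC AUC and
paired AUC comparison (DeLong), and stratified k-fold cross-validated AUC.

The predicted probabilities that feed the AUC, calibration and
reclassification machinery come from a univariable logistic model of the
4-year binary outcome on the score. Patients censored event-free before the
horizon carry no 4-year label; they are excluded with a logged count (a
sensitivity option treats them as non-events).

AUC point estimates use the Mann-Whitney rank formula with the usual 1/2
credit for ties; variances and the paired two-model comparison use DeLong's
structural-component estimator, implemented here with midranks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscriminationReport:
    auc: float
    ci_low: float
    ci_high: float
    cv_auc: float | None = None
    cv_ci_low: float | None = None
    cv_ci_high: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValidationError("AUC confidence interval does not bracket the estimate")


def _check_binary(outcomes: np.ndarray) -> None:
    if outcomes.sum() < 1 or (1 - outcomes).sum() < 1:
        raise ValidationError("need at least one event and one non-event")


def fit_risk_model(
    scores,
    outcomes,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Univariable logistic model of a binary outcome on a score.

    Returns per-patient predicted probabilities and the (intercept, slope)
    coefficients. Predictions are monotone in the score because the model
    has a single linear term.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("scores and outcomes must be matching 1-d arrays")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome is constant; cannot fit a risk model")
    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    except Exception as exc:
        raise ValidationError(
            "logistic risk model failed (possible complete separation; "
            f"consider binning or penalisation): {exc}"
        ) from exc
    return np.asarray(fit.predict(design)), (float(fit.params[0]), float(fit.params[1]))


def binary_outcome_at_horizon(
    times,
    events,
    horizon: float = 4.0,
    censored_as_nonevent: bool = False,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Binary event-by-horizon label from (time, event) follow-up data.

    Returns (keep_mask, labels over kept patients, n_excluded). Patients
    censored event-free before the horizon are excluded by default (their
    4-year status is unknown); ``censored_as_nonevent=True`` keeps them as
    non-events for sensitivity analyses.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    event_by_h = e & (t <= horizon)
    known_nonevent = (~e & (t >= horizon)) | (e & (t > horizon))
    keep = event_by_h | known_nonevent
    if censored_as_nonevent:
        keep = np.ones_like(keep)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d patients censored event-free before the horizon", n_excluded)
    return keep, event_by_h[keep.astype(bool)].astype(int), n_excluded


# -------------------------------------------------------- DeLong machinery

def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    return ranks


def _delong(predictions: np.ndarray, outcomes: np.ndarray):
    """AUCs and DeLong covariance matrix for k models on the same patients.

    ``predictions`` is (k, n); returns (aucs shape (k,), cov shape (k, k)).
    """
    y = np.asarray(outcomes).astype(bool)
    _check_binary(y.astype(float))
    pos = predictions[:, y]
    neg = predictions[:, ~y]
    m, n = pos.shape[1], neg.shape[1]
    k = predictions.shape[0]
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10) if m > 1 else np.zeros((k, k))
    s01 = np.cov(v01) if n > 1 else np.zeros((k, k))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def auc(predictions, outcomes, alpha: float = 0.05) -> DiscriminationReport:
    """Mann-Whitney AUC with a DeLong-variance Wald confidence interval."""
    p = np.asarray(predictions, dtype=float)[None, :]
    aucs, cov = _delong(p, outcomes)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    return DiscriminationReport(
        auc=float(aucs[0]),
        ci_low=float(np.clip(aucs[0] - z * se, 0.0, aucs[0])),
        ci_high=float(np.clip(aucs[0] + z * se, aucs[0], 1.0)),
    )


def compare_auc_paired(pred_a, pred_b, outcomes) -> dict:
    """DeLong paired test of two models' AUCs on the same patients."""
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    y = np.asarray(outcomes)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValidationError("paired AUC comparison requires identical patient sets")
    aucs, cov = _delong(np.vstack([a, b]), y)
    diff = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0:
        z, p = 0.0, 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {
        "auc_a": float(aucs[0]),
        "auc_b": float(aucs[1]),
        "difference": diff,
        "z": float(z),
        "p_value": p,
    }


def cv_auc(
    scores,
    outcomes,
    k: int = 10,
    seed: int = 0,
) -> DiscriminationReport:
    """Cross-validated AUC from pooled out-of-fold logistic predictions.

    Folds are stratified by event status and the risk model is refit on
    each training fold; the single AUC and its DeLong CI are computed on
    the pooled out-of-fold predictions, which is stable when events are
    rare. Deterministic given (data, k, seed).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    _check_binary(y.astype(float))
    if k < 2:
        raise ValidationError("cross-validation requires k >= 2 folds")
    n_events = int(y.sum())
    n_nonevents = int((1 - y).sum())
    k_eff = min(k, n_events, n_nonevents)
    if k_eff < k:
        warnings.warn(
            f"reducing folds from {k} to {k_eff} so every fold has both classes",
            stacklevel=2,
        )
    splitter = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    for train, test in splitter.split(x[:, None], y):
        preds, coef = fit_risk_model(x[train], y[train])
        oof[test] = 1.0 / (1.0 + np.exp(-(coef[0] + coef[1] * x[test])))
    report = auc(oof, y)
    return DiscriminationReport(
        auc=report.auc,
        ci_low=report.ci_low,
        ci_high=report.ci_high,
        cv_auc=report.auc,
        cv_ci_low=report.ci_low,
        cv_ci_high=report.ci_high,
    )
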