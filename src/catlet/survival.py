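"""Tertile stratification and survival analysis for score validation.

Cohorts are split into score tertiles (low/mid/top), event-free survival is
summarised with Kaplan-Meier curves compared by the log-rank test, event
rates across ordered tertiles are tested for trend with a Cochran-Armitage
score test, and effect sizes come from Cox proportional-hazards models —
either per standard deviation of the continuous score or per tertile against
the low tertile, crude or adjusted for a configurable covariate set.

Kaplan-Meier, log-rank and Cox fitting are delegated to lifelines (Efron
tie handling); the tertile logic, trend test and per-SD standardisation are
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import ValidationError

FOLLOW_UP_HORIZON_YEARS = 4.0

ENDPOINTS = (
    "mace",
    "all_cause_death",
    "cardiac_death",
    "myocardial_infarction",
    "revascularization",
)

TERTILE_LABELS = ("low", "mid", "top")


@dataclass(frozen=True)
class TertileAssignment:
    bounds: tuple[float, float]
    labels: np.ndarray  # dtype object, values in TERTILE_LABELS

    def counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in TERTILE_LABELS}


@dataclass(frozen=True)
class EffectEstimate:
    """Hazard ratio with Wald 95% CI and p-value."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    scale: Literal["per_sd", "tertile_vs_low"]
    sd_used: float | None = None
    term: str = ""

    def __post_init__(self) -> None:
        if not self.ci_low <= self.hazard_ratio <= self.ci_high:
            raise ValidationError(
                f"inconsistent CI: {self.ci_low} <= {self.hazard_ratio} <= {self.ci_high}"
            )


def assign_tertiles(
    scores: Sequence[float],
    explicit_bounds: tuple[float, float] | None = None,
) -> TertileAssignment:
    """Split scores into low/mid/top with left-open right-closed intervals.

    ``score <= b1`` is low, ``b1 < score <= b2`` mid, ``score > b2`` top.
    Bounds default to the empirical 1/3 and 2/3 quantiles; explicit bounds
    (e.g. the registry tertiles CS<=12 / 13-18 / >=19, i.e. bounds (12, 18))
    override them.
    """
    scores = np.asarray(scores, dtype=float)
    if explicit_bounds is None:
        if scores.size < 3:
            raise ValidationError("need n >= 3 scores to compute empirical tertiles")
        b1, b2 = np.quantile(scores, [1 / 3, 2 / 3])
    else:
        b1, b2 = map(float, explicit_bounds)
        if b1 > b2:
            raise ValidationError(f"tertile bounds must be ordered, got ({b1}, {b2})")
    if b1 == b2:
        warnings.warn(
            "degenerate tertile bounds: scores are concentrated; "
            "categories will not partition the cohort into thirds",
            stacklevel=2,
        )
    labels = np.where(scores <= b1, "low", np.where(scores <= b2, "mid", "top"))
    return TertileAssignment(bounds=(float(b1), float(b2)), labels=labels.astype(object))


def km_estimate(
    times: Sequence[float], events: Sequence[bool]
) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a frame with columns ``time``, ``survival`` and ``at_risk``
    (right-continuous step values at the observed times, S(0)=1 implied).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("km_estimate requires at least one observation")
    if np.any(times <= 0):
        raise ValidationError("event/censoring times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
    return pd.DataFrame(
        {"time": surv.index.values, "survival": surv.values, "at_risk": at_risk.values}
    )


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[bool]]]):
    """k-sample log-rank test; returns (chi2 statistic, df, p)."""
    if len(groups) < 2:
        raise ValidationError("log-rank test requires at least two groups")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, dtype=bool) for _, e in groups])
    labels = np.concatenate(
        [np.full(len(np.atleast_1d(t)), i) for i, (t, _) in enumerate(groups)]
    )
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def trend_test(
    event_counts: Sequence[int], totals: Sequence[int]
) -> tuple[float, float]:
    """Cochran-Armitage test for trend in event rates across ordered groups.

    Scores the k ordered groups 1..k and tests a linear trend in the event
    proportion; returns the signed z statistic (positive = increasing rate)
    and the two-sided p-value.
    """
    events = np.asarray(event_counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if events.shape != totals.shape or events.ndim != 1 or events.size < 2:
        raise ValidationError("need matching 1-d event counts and totals, k >= 2")
    if np.any(totals <= 0):
        raise ValidationError("every group total must be > 0")
    if np.any(events < 0) or np.any(events > totals):
        raise ValidationError("event counts must lie in [0, total] per group")
    scores = np.arange(1.0, events.size + 1.0)
    n = totals.sum()
    p = events.sum() / n
    s_bar = (scores * totals).sum() / n
    numerator = (scores * events).sum() - p * (scores * totals).sum()
    variance = p * (1 - p) * ((scores - s_bar) ** 2 * totals).sum()
    if variance == 0:
        raise ValidationError("trend test degenerate: all events or none, or one group")
    z = numerator / np.sqrt(variance)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def cox_effect(
    data: pd.DataFrame,
    predictor: str,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: Sequence[str] = (),
    scale: Literal["per_sd", "tertile_vs_low"] = "per_sd",
    sd: float | None = None,
) -> list[EffectEstimate]:
    """Cox proportional-hazards effect of a score (or its tertile) on an endpoint.

    ``scale="per_sd"`` standardises the continuous predictor by ``sd`` (the
    cohort SD when not given) so the hazard ratio reads per 1 SD higher
    score. ``scale="tertile_vs_low"`` expects a categorical predictor with
    labels low/mid/top and reports mid-vs-low and top-vs-low. Ties are
    handled with the Efron approximation (lifelines default).
    """
    df = data[[duration_col, event_col, predictor, *covariates]].copy()
    if df.isna().any().any():
        missing = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"missing values in model columns {missing}")
    if scale == "per_sd":
        values = df[predictor].astype(float)
        sd_used = float(values.std(ddof=1)) if sd is None else float(sd)
        if not sd_used > 0:
            raise ValidationError(f"predictor {predictor!r} has zero variance")
        df[predictor] = values / sd_used
        terms = [predictor]
    elif scale == "tertile_vs_low":
        labels = df[predictor].astype(str)
        unknown = set(labels.unique()) - set(TERTILE_LABELS)
        if unknown:
            raise ValidationError(f"unexpected tertile labels {sorted(unknown)}")
        df["tertile_mid"] = (labels == "mid").astype(float)
        df["tertile_top"] = (labels == "top").astype(float)
        df = df.drop(columns=[predictor])
        terms = ["tertile_mid", "tertile_top"]
        sd_used = None
    else:
        raise ValidationError(f"unknown scale {scale!r}")

    for col in covariates:
        if df[col].astype(float).std(ddof=1) == 0:
            raise ValidationError(f"covariate {col!r} has zero variance")

    cph = CoxPHFitter()
    try:
        # retry with a damped Newton step when the default step oscillates
        for step_size in (None, 0.25):
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                try:
                    fit_options = {} if step_size is None else {"step_size": step_size}
                    cph.fit(
                        df,
                        duration_col=duration_col,
                        event_col=event_col,
                        fit_options=fit_options,
                    )
                    break
                except ConvergenceWarning:
                    if step_size is not None:
                        raise
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValidationError(f"Cox model failed to converge: {exc}") from exc

    out = []
    for term in terms:
        s = cph.summary.loc[term]
        out.append(
            EffectEstimate(
                hazard_ratio=float(s["exp(coef)"]),
                ci_low=float(s["exp(coef) lower 95%"]),
                ci_high=float(s["exp(coef) upper 95%"]),
                p_value=float(s["p"]),
                scale=scale,
                sd_used=sd_used,
                term=term,
            )
        )
    return out
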