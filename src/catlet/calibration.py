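"""Calibration of predicted risks against observed outcomes.

Three complementary views:

* calibration-in-the-large (CITL): the intercept of a logistic
  recalibration model with the predicted logit as an offset — 0 means
  predictions are right on average; negative means over-estimation,
  positive under-estimation;
* calibration slope: the coefficient on the predicted logit in a logistic
  recalibration — 1 means the spread of predictions is right, <1 means
  predictions are too extreme;
* Hosmer-Lemeshow: a chi-square goodness-of-fit statistic over deciles of
  predicted risk, with g-2 degrees of freedom for g groups.

A lowess smooth of observed outcome on predicted risk is attached for
calibration plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError

_CLIP = 1e-9


@dataclass(frozen=True)
class CalibrationReport:
    intercept: float          # CITL
    slope: float
    hl_statistic: float
    hl_df: int
    hl_p: float
    bins: list[tuple[float, float, int]] = field(repr=False)  # (mean pred, obs rate, n)
    lowess_curve: np.ndarray | None = field(default=None, repr=False)


def _prepare(predictions, outcomes) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValidationError("predictions and outcomes must be matching 1-d arrays")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("predicted probabilities must lie in [0, 1]")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(
            "predictions at 0 or 1 clipped for logit transform", stacklevel=3
        )
        p = np.clip(p, _CLIP, 1 - _CLIP)
    return p, y


def hosmer_lemeshow(
    predictions, outcomes, n_bins: int = 10
) -> tuple[float, int, float, list[tuple[float, float, int]]]:
    """Hosmer-Lemeshow chi-square over groups of predicted risk.

    Groups are deciles of risk (equal-count quantile bins, merged when
    predictions tie); statistic is referred to chi-square with g-2 df.
    """
    p, y = _prepare(predictions, outcomes)
    quantiles = np.quantile(p, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(quantiles)
    if len(edges) - 1 < 2:
        raise ValidationError("predictions too concentrated to form risk groups")
    groups = np.clip(np.searchsorted(edges, p, side="left") - 1, 0, len(edges) - 2)
    statistic = 0.0
    bins: list[tuple[float, float, int]] = []
    for g in np.unique(groups):
        mask = groups == g
        n_g = int(mask.sum())
        observed = float(y[mask].sum())
        expected = float(p[mask].sum())
        mean_p = expected / n_g
        denom = expected * (1 - mean_p)
        if denom > 0:
            statistic += (observed - expected) ** 2 / denom
        bins.append((mean_p, observed / n_g, n_g))
    df = len(bins) - 2
    return float(statistic), df, float(stats.chi2.sf(statistic, df)), bins


def calibration(
    predictions,
    outcomes,
    n_bins: int = 10,
    lowess_fraction: float = 2 / 3,
    with_lowess: bool = True,
) -> CalibrationReport:
    """Full calibration assessment of predicted probabilities.

    CITL is the intercept of a logistic model of the outcome with the
    predicted logit as offset; the slope comes from a logistic model of the
    outcome on the predicted logit. The lowess curve (observed outcome on
    predicted risk, 3 robustifying iterations) is presentational only.
    """
    p, y = _prepare(predictions, outcomes)
    logit = np.log(p / (1 - p))

    citl_fit = sm.GLM(
        y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=logit
    ).fit()
    slope_fit = sm.GLM(
        y, sm.add_constant(logit), family=sm.families.Binomial()
    ).fit()

    hl_stat, hl_df, hl_p, bins = hosmer_lemeshow(p, y, n_bins=n_bins)
    curve = None
    if with_lowess:
        curve = sm.nonparametric.lowess(y, p, frac=lowess_fraction, it=3)
    return CalibrationReport(
        intercept=float(citl_fit.params[0]),
        slope=float(slope_fit.params[1]),
        hl_statistic=hl_stat,
        hl_df=hl_df,
        hl_p=hl_p,
        bins=bins,
        lowess_curve=curve,
    )
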