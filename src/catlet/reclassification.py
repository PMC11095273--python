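"""Reclassification metrics: category-dependent and category-free net
reclassification improvement (NRI) and integrated discrimination
improvement (IDI).

When a new risk model replaces an old one, patients move between risk
categories. Movement upward is correct for patients who go on to have the
event and incorrect for those who do not; the category-dependent NRI nets
these movements within events and non-events:

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)]

Risk categories follow the half / one / two times the event rate rule
(e.g. event rate 20% -> cutoffs 10%, 20%, 40% -> four categories), with
left-open right-closed intervals. The category-free NRI replaces category
movement with any change in predicted risk (ties count as no movement),
and the IDI is the difference in discrimination slopes — mean predicted
risk in events minus non-events — between the two models, which equals the
NRI integrated over all possible cutoffs.

Z statistics use the Pencina (2008) asymptotic standard errors; an
uncorrected "simple" variant (omitting the -(net)^2/n^3 terms) is also
exposed since published analyses differ in which they use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

VarianceVariant = Literal["pencina", "simple"]


@dataclass(frozen=True)
class RiskCutoffs:
    """Strictly increasing probability thresholds defining k+1 categories."""

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t:
            raise ValidationError("at least one cutoff required")
        if any(not 0 < x < 1 for x in t):
            raise ValidationError(f"cutoffs must lie in (0, 1), got {t}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError(f"cutoffs must be strictly increasing, got {t}")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    def labels(self) -> list[str]:
        t = self.thresholds
        return [f"<={t[0]:.0%}"] + [f"{a:.0%}~" for a in t]


@dataclass(frozen=True)
class ReclassificationTable:
    """Paired old-model x new-model category counts, split by event status."""

    events: np.ndarray = field(repr=False)      # (k, k) counts, rows = old category
    nonevents: np.ndarray = field(repr=False)
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ev = np.asarray(self.events)
        ne = np.asarray(self.nonevents)
        if ev.shape != ne.shape or ev.ndim != 2 or ev.shape[0] != ev.shape[1]:
            raise ValidationError("event and non-event matrices must be square and matched")
        if np.any(ev < 0) or np.any(ne < 0):
            raise ValidationError("reclassification counts must be non-negative")

    @property
    def n_events(self) -> int:
        return int(np.asarray(self.events).sum())

    @property
    def n_nonevents(self) -> int:
        return int(np.asarray(self.nonevents).sum())

    @staticmethod
    def _movements(matrix: np.ndarray) -> tuple[int, int]:
        m = np.asarray(matrix)
        up = int(np.triu(m, k=1).sum())
        down = int(np.tril(m, k=-1).sum())
        return up, down

    def movements(self) -> dict[str, int]:
        up_e, down_e = self._movements(self.events)
        up_ne, down_ne = self._movements(self.nonevents)
        return {
            "events_up": up_e,
            "events_down": down_e,
            "nonevents_up": up_ne,
            "nonevents_down": down_ne,
        }


@dataclass(frozen=True)
class NriIdiReport:
    nri: float
    event_nri: float
    nonevent_nri: float
    z: float
    p_value: float
    kind: str = "category"


def derive_cutoffs(
    event_rate: float,
    mode: Literal["exact", "explicit"] = "exact",
    explicit_values: Sequence[float] | None = None,
) -> RiskCutoffs:
    """Cutoffs at half, one and two times the event rate (or explicit).

    ``mode="exact"`` requires event_rate < 0.5 so the top cutoff stays below
    1; ``mode="explicit"`` accepts supplied thresholds verbatim (used e.g.
    for rounded published cutoffs such as 10%/20%/40%).
    """
    if mode == "explicit":
        if not explicit_values:
            raise ValidationError("explicit mode requires explicit_values")
        return RiskCutoffs(tuple(float(v) for v in explicit_values))
    if not 0 < event_rate < 0.5:
        raise ValidationError(
            f"exact cutoff rule needs 0 < event rate < 0.5 (got {event_rate}); "
            "use mode='explicit' for higher rates"
        )
    return RiskCutoffs((event_rate / 2, event_rate, 2 * event_rate))


def categorize(predictions, cutoffs: RiskCutoffs) -> np.ndarray:
    """Map predicted probabilities to category indices 0..k.

    Intervals are left-open right-closed: a prediction exactly at a cutoff
    falls in the lower category (<=10%, 10%-<=20%, ...).
    """
    p = np.asarray(predictions, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("predictions must lie in [0, 1]")
    return np.searchsorted(np.asarray(cutoffs.thresholds), p, side="left").astype(int)


def build_reclass_table(
    pred_old, pred_new, outcomes, cutoffs: RiskCutoffs
) -> ReclassificationTable:
    """Cross-tabulate old vs new risk category, split by event status."""
    po = np.asarray(pred_old, dtype=float)
    pn = np.asarray(pred_new, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    if not (po.shape == pn.shape == y.shape):
        raise ValidationError("paired predictions and outcomes must be matched 1-d arrays")
    k = cutoffs.n_categories
    cat_old = categorize(po, cutoffs)
    cat_new = categorize(pn, cutoffs)
    events = np.zeros((k, k), dtype=int)
    nonevents = np.zeros((k, k), dtype=int)
    np.add.at(events, (cat_old[y], cat_new[y]), 1)
    np.add.at(nonevents, (cat_old[~y], cat_new[~y]), 1)
    return ReclassificationTable(
        events=events, nonevents=nonevents, labels=tuple(cutoffs.labels())
    )


def _nri_z(
    up_e: float, down_e: float, n_e: int,
    up_ne: float, down_ne: float, n_ne: int,
    variance: VarianceVariant,
) -> tuple[float, float, float, float]:
    if n_e == 0 or n_ne == 0:
        raise ValidationError("NRI requires at least one event and one non-event")
    event_nri = (up_e - down_e) / n_e
    nonevent_nri = (down_ne - up_ne) / n_ne
    var = (up_e + down_e) / n_e**2 + (up_ne + down_ne) / n_ne**2
    if variance == "pencina":
        var -= (up_e - down_e) ** 2 / n_e**3 + (down_ne - up_ne) ** 2 / n_ne**3
    elif variance != "simple":
        raise ValidationError(f"unknown variance variant {variance!r}")
    nri = event_nri + nonevent_nri
    z = nri / np.sqrt(var) if var > 0 else 0.0
    return event_nri, nonevent_nri, float(z), float(2 * stats.norm.sf(abs(z)))


def category_nri(
    table: ReclassificationTable, variance: VarianceVariant = "pencina"
) -> NriIdiReport:
    """Category-dependent NRI from a paired reclassification table."""
    m = table.movements()
    event_nri, nonevent_nri, z, p = _nri_z(
        m["events_up"], m["events_down"], table.n_events,
        m["nonevents_up"], m["nonevents_down"], table.n_nonevents,
        variance,
    )
    return NriIdiReport(
        nri=event_nri + nonevent_nri,
        event_nri=event_nri,
        nonevent_nri=nonevent_nri,
        z=z,
        p_value=p,
        kind="category",
    )


def category_free_nri(
    pred_old, pred_new, outcomes, variance: VarianceVariant = "pencina"
) -> NriIdiReport:
    """Continuous NRI: any change of predicted risk in the correct
    direction counts as improvement; ties count as no movement."""
    po = np.asarray(pred_old, dtype=float)
    pn = np.asarray(pred_new, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    if not (po.shape == pn.shape == y.shape):
        raise ValidationError("paired predictions and outcomes must be matched 1-d arrays")
    up = pn > po
    down = pn < po
    n_e = int(y.sum())
    n_ne = int((~y).sum())
    event_nri, nonevent_nri, z, p = _nri_z(
        int((up & y).sum()), int((down & y).sum()), n_e,
        int((up & ~y).sum()), int((down & ~y).sum()), n_ne,
        variance,
    )
    return NriIdiReport(
        nri=event_nri + nonevent_nri,
        event_nri=event_nri,
        nonevent_nri=nonevent_nri,
        z=z,
        p_value=p,
        kind="category_free",
    )


def discrimination_slope(predictions, outcomes) -> float:
    """Mean predicted risk in events minus mean in non-events."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValidationError("discrimination slope needs both events and non-events")
    return float(p[y].mean() - p[~y].mean())


def idi(pred_old, pred_new, outcomes) -> NriIdiReport:
    """Integrated discrimination improvement.

    IDI = [mean(new|events) - mean(new|non-events)]
        - [mean(old|events) - mean(old|non-events)],
    i.e. the difference of the two models' discrimination slopes. The Z
    statistic uses the standard errors of the per-patient prediction
    differences within events and within non-events.
    """
    po = np.asarray(pred_old, dtype=float)
    pn = np.asarray(pred_new, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    if not (po.shape == pn.shape == y.shape):
        raise ValidationError("paired predictions and outcomes must be matched 1-d arrays")
    n_e = int(y.sum())
    n_ne = int((~y).sum())
    if n_e == 0 or n_ne == 0:
        raise ValidationError("IDI requires at least one event and one non-event")
    diff = pn - po
    idi_value = float(diff[y].mean() + (-diff[~y]).mean())
    se_e = diff[y].std(ddof=1) / np.sqrt(n_e) if n_e > 1 else 0.0
    se_ne = diff[~y].std(ddof=1) / np.sqrt(n_ne) if n_ne > 1 else 0.0
    se = float(np.sqrt(se_e**2 + se_ne**2))
    z = idi_value / se if se > 0 else 0.0
    return NriIdiReport(
        nri=idi_value,
        event_nri=float(diff[y].mean()),
        nonevent_nri=float((-diff[~y]).mean()),
        z=float(z),
        p_value=float(2 * stats.norm.sf(abs(z))),
        kind="idi",
    )
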