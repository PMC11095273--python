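"""End-to-end validation pipeline.

Runs, for each endpoint and for both models (CatLet score and Clinical
CatLet score): scoring, tertile stratification with Kaplan-Meier / log-rank
/ trend tests, crude and adjusted Cox effects (per SD and per tertile),
logistic risk models with apparent and cross-validated AUC, calibration,
and CS-vs-CCS comparison (paired AUC test, reclassification NRI/IDI).
The report is a plain nested dict (JSON-serialisable), deterministic given
the inputs and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibration import calibration
from .discrimination import (
    auc,
    binary_outcome_at_horizon,
    compare_auc_paired,
    cv_auc,
    fit_risk_model,
)
from .errors import ValidationError
from .reclassification import (
    build_reclass_table,
    category_free_nri,
    category_nri,
    derive_cutoffs,
    idi,
)
from .scoring import (
    CreatinineUnit,
    OcclusionMode,
    PatientRecord,
    UMOL_PER_MG_DL,
    score_patient,
)
from .survival import assign_tertiles, cox_effect, km_estimate, logrank_test, trend_test
from .weights import SegmentWeightTable

logger = logging.getLogger(__name__)

#: adjustment covariate sets; CCS models drop age/creatinine/LVEF because
#: those enter the score itself (collinearity)
CS_ADJUSTMENT = (
    "age", "sex_male", "hypertension", "diabetes", "prior_stroke",
    "smoking_current", "smoking_past", "creatinine_mg_dl", "lvef",
    "heavy_calcification",
)
CCS_ADJUSTMENT = (
    "sex_male", "hypertension", "diabetes", "prior_stroke",
    "smoking_current", "smoking_past", "heavy_calcification",
)


@dataclass(frozen=True)
class PipelineConfig:
    endpoints: Sequence[str] = ("mace",)
    occlusion_mode: OcclusionMode = "force_non_occlusive"
    tertile_bounds: dict | None = None        # {"cs": (b1,b2), "ccs": (b1,b2)} or None
    cutoff_mode: str = "exact"                # "exact" | "explicit"
    explicit_cutoffs: tuple[float, ...] | None = None
    cv_folds: int = 10
    seed: int = 0
    adjusted: bool = True
    horizon: float = 4.0


def cohort_frame(
    patients: Sequence[PatientRecord],
    table: SegmentWeightTable,
    occlusion_mode: OcclusionMode = "force_non_occlusive",
) -> pd.DataFrame:
    """Patient-level analysis frame: scores plus numeric covariates."""
    rows = []
    for p in patients:
        s = score_patient(p, table, occlusion_mode)
        creat_mg = (
            p.creatinine / UMOL_PER_MG_DL
            if p.creatinine_unit is CreatinineUnit.UMOL_PER_L
            else p.creatinine
        )
        rows.append({
            "patient_id": p.patient_id,
            "cs": s.catlet_score,
            "acef": s.acef,
            "ccs": s.clinical_catlet_score,
            "age": p.age,
            "sex_male": float(p.sex == "male"),
            "lvef": p.lvef,
            "creatinine_mg_dl": creat_mg,
            "hypertension": float(p.hypertension),
            "diabetes": float(p.diabetes),
            "prior_stroke": float(p.prior_stroke),
            "smoking_current": float(p.smoking == "current"),
            "smoking_past": float(p.smoking == "past"),
            "heavy_calcification": float(any(l.heavy_calcification for l in p.lesions)),
        })
    return pd.DataFrame(rows)


def _survival_block(df: pd.DataFrame, score_col: str, bounds, covariates, adjusted):
    tert = assign_tertiles(df[score_col].to_numpy(), explicit_bounds=bounds)
    df = df.assign(tertile=tert.labels)
    groups = [
        (g["time"].to_numpy(), g["event"].to_numpy())
        for _, g in df.groupby("tertile", sort=True)
    ]
    block: dict = {
        "tertile_bounds": list(tert.bounds),
        "tertile_counts": tert.counts(),
    }
    if len(groups) >= 2:
        chi2, dof, p = logrank_test(groups)
        block["logrank"] = {"chi2": chi2, "df": dof, "p": p}
        counts = df.groupby("tertile", sort=True).agg(
            events=("event", "sum"), total=("event", "size")
        )
        order = [t for t in ("low", "mid", "top") if t in counts.index]
        z, p_trend = trend_test(
            counts.loc[order, "events"].tolist(), counts.loc[order, "total"].tolist()
        )
        block["trend"] = {"z": z, "p": p_trend}
    block["km"] = {
        label: km_estimate(g["time"], g["event"]).to_dict(orient="list")
        for label, g in df.groupby("tertile", sort=True)
    }
    per_sd = cox_effect(df, score_col, scale="per_sd")[0]
    block["cox_per_sd_crude"] = dataclasses.asdict(per_sd)
    if len(set(tert.labels)) == 3:
        block["cox_tertile_crude"] = [
            dataclasses.asdict(e)
            for e in cox_effect(df, "tertile", scale="tertile_vs_low")
        ]
    if adjusted:
        block["cox_per_sd_adjusted"] = dataclasses.asdict(
            cox_effect(df, score_col, covariates=list(covariates), scale="per_sd")[0]
        )
    return block


def run_pipeline(
    patients: Sequence[PatientRecord],
    outcomes: pd.DataFrame,
    table: SegmentWeightTable,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Run the full validation pipeline; returns a JSON-ready report."""
    frame = cohort_frame(patients, table, config.occlusion_mode)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_patients": len(frame),
        "scores": {
            col: {
                "mean": float(frame[col].mean()),
                "sd": float(frame[col].std(ddof=1)),
                "median": float(frame[col].median()),
                "iqr": [float(frame[col].quantile(q)) for q in (0.25, 0.75)],
            }
            for col in ("cs", "acef", "ccs")
        },
        "endpoints": {},
    }
    models = {"cs": CS_ADJUSTMENT, "ccs": CCS_ADJUSTMENT}
    for endpoint in config.endpoints:
        sub = outcomes[outcomes["endpoint"] == endpoint]
        if sub.empty:
            raise ValidationError(f"no outcome rows for endpoint {endpoint!r}")
        df = frame.merge(sub[["patient_id", "event", "time"]], on="patient_id")
        if len(df) != len(frame):
            raise ValidationError(f"{endpoint}: outcomes do not cover the cohort")
        ep_report: dict = {"n_events": int(df["event"].sum())}

        keep, labels, n_excluded = binary_outcome_at_horizon(
            df["time"], df["event"], horizon=config.horizon
        )
        ep_report["n_excluded_censored_before_horizon"] = n_excluded
        binary_df = df[keep.astype(bool)]
        event_rate = float(labels.mean())
        ep_report["event_rate_4y"] = event_rate

        predictions = {}
        for score_col, covs in models.items():
            bounds = (config.tertile_bounds or {}).get(score_col)
            block = _survival_block(df, score_col, bounds, covs, config.adjusted)
            preds, coef = fit_risk_model(binary_df[score_col], labels)
            predictions[score_col] = preds
            block["risk_model_coefficients"] = {"intercept": coef[0], "slope": coef[1]}
            block["auc_apparent"] = dataclasses.asdict(auc(preds, labels))
            block["auc_cv"] = dataclasses.asdict(
                cv_auc(binary_df[score_col], labels, k=config.cv_folds, seed=config.seed)
            )
            cal = calibration(preds, labels, with_lowess=False)
            block["calibration"] = {
                "intercept": cal.intercept,
                "slope": cal.slope,
                "hl_statistic": cal.hl_statistic,
                "hl_df": cal.hl_df,
                "hl_p": cal.hl_p,
            }
            ep_report[score_col] = block

        if config.cutoff_mode == "explicit":
            cutoffs = derive_cutoffs(event_rate, "explicit", config.explicit_cutoffs)
        else:
            cutoffs = derive_cutoffs(event_rate, "exact")
        pred_old, pred_new = predictions["cs"], predictions["ccs"]
        rtab = build_reclass_table(pred_old, pred_new, labels, cutoffs)
        comparison = {
            "paired_auc": compare_auc_paired(pred_old, pred_new, labels),
            "cutoffs": list(cutoffs.thresholds),
            "reclassification_table": {
                "events": np.asarray(rtab.events).tolist(),
                "nonevents": np.asarray(rtab.nonevents).tolist(),
                "movements": rtab.movements(),
            },
            "category_nri": dataclasses.asdict(category_nri(rtab)),
            "category_free_nri": dataclasses.asdict(
                category_free_nri(pred_old, pred_new, labels)
            ),
            "idi": dataclasses.asdict(idi(pred_old, pred_new, labels)),
        }
        ep_report["cs_vs_ccs"] = comparison
        report["endpoints"][endpoint] = ep_report
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
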