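"""Cohort and outcome file I/O.

Cohort CSV: one row per lesion, patient-level columns repeated. Creatinine
units travel in the column name (``creatinine_umol_per_L`` or
``creatinine_mg_per_dL``). Headers are validated strictly: missing required
columns are an error, unknown columns a warning; malformed values are
collected per row and reported together.

Outcome CSV: long format with columns patient_id, endpoint, event, time.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .patterns import resolve_pattern
from .scoring import CreatinineUnit, LesionRecord, PatientRecord

_PATIENT_COLS = [
    "patient_id", "age", "sex", "lvef",
    "lad_length", "diagonal_size", "dominance",
    "hypertension", "diabetes", "prior_stroke", "smoking", "alcohol",
]
_LESION_COLS = [
    "segment_id", "stenosis_pct", "occlusive", "vessel_diameter_mm",
    "heavy_calcification", "length_gt_20mm", "bifurcation", "trifurcation",
    "aorto_ostial", "angulation_lt_70", "severe_tortuosity", "high_thrombus_burden",
]
_CREATININE_COLS = {
    "creatinine_umol_per_L": CreatinineUnit.UMOL_PER_L,
    "creatinine_mg_per_dL": CreatinineUnit.MG_PER_DL,
}
_REQUIRED = ["patient_id", "age", "sex", "lvef", "lad_length", "diagonal_size",
             "dominance", "segment_id", "stenosis_pct", "occlusive",
             "vessel_diameter_mm"]
_BOOL_LESION_FLAGS = _LESION_COLS[4:]


def write_cohort(patients, path: str | Path) -> None:
    """Write patient records as a one-row-per-lesion CSV (lossless)."""
    rows = []
    for p in patients:
        base = {
            "patient_id": p.patient_id,
            "age": p.age,
            "sex": p.sex,
            "lvef": p.lvef,
            ("creatinine_umol_per_L" if p.creatinine_unit is CreatinineUnit.UMOL_PER_L
             else "creatinine_mg_per_dL"): p.creatinine,
            "lad_length": p.pattern.lad_length.value,
            "diagonal_size": p.pattern.diagonal_size.value,
            "dominance": p.pattern.dominance.value,
            "hypertension": p.hypertension,
            "diabetes": p.diabetes,
            "prior_stroke": p.prior_stroke,
            "smoking": p.smoking,
            "alcohol": p.alcohol,
        }
        for lesion in p.lesions:
            row = dict(base)
            for col in _LESION_COLS:
                row[col] = getattr(lesion, col)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path: str | Path) -> tuple[list[PatientRecord], dict]:
    """Read a cohort CSV into typed patient records.

    Returns ``(patients, report)`` where the report carries warnings and the
    count of rows read. Per-row parse failures are collected and raised
    together, naming the offending rows (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    report: dict = {"n_rows": len(df), "warnings": []}

    creat_cols = [c for c in df.columns if c in _CREATININE_COLS]
    if len(creat_cols) != 1:
        raise ValidationError(
            f"cohort CSV must have exactly one creatinine column of "
            f"{sorted(_CREATININE_COLS)}, found {creat_cols}"
        )
    unit = _CREATININE_COLS[creat_cols[0]]

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing required columns: {missing}")
    known = set(_PATIENT_COLS) | set(_LESION_COLS) | set(_CREATININE_COLS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        msg = f"ignoring unknown columns: {unknown}"
        report["warnings"].append(msg)
        warnings.warn(msg, stacklevel=2)

    errors: list[str] = []
    patients: list[PatientRecord] = []
    for pid, group in df.groupby("patient_id", sort=False):
        first = group.iloc[0]
        lesions = []
        for idx, row in group.iterrows():
            try:
                lesions.append(LesionRecord(
                    segment_id=str(row["segment_id"]),
                    stenosis_pct=float(row["stenosis_pct"]),
                    occlusive=_parse_bool(row["occlusive"]),
                    vessel_diameter_mm=float(row["vessel_diameter_mm"]),
                    **{
                        flag: _parse_bool(row[flag]) if flag in row else False
                        for flag in _BOOL_LESION_FLAGS
                    },
                ))
            except (TypeError, ValueError) as exc:
                errors.append(f"row {idx + 1}: {exc}")
        try:
            patients.append(PatientRecord(
                patient_id=str(pid),
                age=float(first["age"]),
                sex=str(first["sex"]),
                lvef=float(first["lvef"]),
                creatinine=float(first[creat_cols[0]]),
                creatinine_unit=unit,
                pattern=resolve_pattern(
                    first["lad_length"], first["diagonal_size"], first["dominance"]
                ),
                lesions=tuple(lesions),
                hypertension=_parse_bool(first.get("hypertension", False)),
                diabetes=_parse_bool(first.get("diabetes", False)),
                prior_stroke=_parse_bool(first.get("prior_stroke", False)),
                smoking=str(first.get("smoking", "never")),
                alcohol=str(first.get("alcohol", "never")),
            ))
        except (TypeError, ValueError) as exc:
            errors.append(f"patient {pid}: {exc}")
    if errors:
        raise ValidationError(
            "cohort CSV has invalid rows:\n  " + "\n  ".join(errors[:20])
        )
    report["n_patients"] = len(patients)
    return patients, report


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no", "nan"}:
        return False
    raise ValueError(f"cannot parse boolean value {value!r}")


def write_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    outcomes.to_csv(path, index=False)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "endpoint", "event", "time"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"outcome CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    df["event"] = df["event"].map(_parse_bool)
    df["time"] = df["time"].astype(float)
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0].tolist()[:10]
        raise ValidationError(f"non-positive follow-up times at rows {bad}")
    return df
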