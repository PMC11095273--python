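"""CatLet score (CS), ACEF I, and Clinical CatLet score (CCS).

The CatLet score sums, over scoreable lesions, the myocardial-supply weight
of the lesion's coronary segment times a stenosis multiplier: 2.0 for a
non-occlusive lesion, 5.0 for a total occlusion. Which weight applies
depends on the patient's coronary circulation pattern (one of 54). The
ACEF I score is age(years)/LVEF(%) plus 1 if serum creatinine is at least
2 mg/dL, and the Clinical CatLet score is the product CS x ACEF I, folding
clinical risk into the anatomic score.

Only lesions meeting the angiographic inclusion rule (>=50% diameter
stenosis in a vessel > 1.5 mm) are scored; adverse lesion descriptors
(calcification, length, bifurcation, ...) are recorded but never scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Sequence

from .errors import ValidationError
from .patterns import CoronaryPatternKey
from .weights import SegmentWeightTable

logger = logging.getLogger(__name__)

NON_OCCLUSIVE_MULTIPLIER = 2.0
OCCLUSIVE_MULTIPLIER = 5.0

#: inclusion rule: >=50% diameter stenosis in a vessel strictly > 1.5 mm
MIN_STENOSIS_PCT = 50.0
MIN_VESSEL_DIAMETER_MM = 1.5

#: creatinine threshold for the ACEF renal term, mg/dL (inclusive)
CREATININE_THRESHOLD_MG_DL = 2.0
UMOL_PER_MG_DL = 88.4

OcclusionMode = Literal["as_recorded", "force_non_occlusive"]


class CreatinineUnit(str, Enum):
    UMOL_PER_L = "umol_per_L"
    MG_PER_DL = "mg_per_dL"


@dataclass(frozen=True)
class LesionRecord:
    """One angiographic lesion. Adverse descriptors are recorded, not scored."""

    segment_id: str
    stenosis_pct: float
    occlusive: bool = False
    vessel_diameter_mm: float | None = None
    heavy_calcification: bool = False
    length_gt_20mm: bool = False
    bifurcation: bool = False
    trifurcation: bool = False
    aorto_ostial: bool = False
    angulation_lt_70: bool = False
    severe_tortuosity: bool = False
    high_thrombus_burden: bool = False

    def __post_init__(self) -> None:
        if self.stenosis_pct is None:
            raise ValidationError(f"lesion {self.segment_id!r}: stenosis_pct is missing")
        if not 0.0 <= self.stenosis_pct <= 100.0:
            raise ValidationError(
                f"lesion {self.segment_id!r}: stenosis_pct must be in [0, 100], "
                f"got {self.stenosis_pct}"
            )
        if self.occlusive and self.stenosis_pct != 100.0:
            raise ValidationError(
                f"lesion {self.segment_id!r}: occlusive lesions have 100% stenosis, "
                f"got {self.stenosis_pct}"
            )


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: float
    sex: str
    lvef: float
    creatinine: float
    creatinine_unit: CreatinineUnit
    pattern: CoronaryPatternKey
    lesions: Sequence[LesionRecord] = field(default_factory=tuple)
    hypertension: bool = False
    diabetes: bool = False
    prior_stroke: bool = False
    smoking: str = "never"
    alcohol: str = "never"

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValidationError(f"patient {self.patient_id}: age must be > 0")
        if not 0 < self.lvef <= 100:
            raise ValidationError(f"patient {self.patient_id}: lvef must be in (0, 100]")
        if not self.creatinine > 0:
            raise ValidationError(f"patient {self.patient_id}: creatinine must be > 0")


@dataclass(frozen=True)
class ScoreSet:
    """CS, ACEF I and CCS for one patient; CCS == CS * ACEF by construction."""

    catlet_score: float
    acef: float
    clinical_catlet_score: float


def eligible_lesion(lesion: LesionRecord) -> bool:
    """Angiographic inclusion rule: >=50% stenosis in a vessel > 1.5 mm."""
    if lesion.vessel_diameter_mm is None:
        raise ValidationError(
            f"lesion {lesion.segment_id!r}: vessel_diameter_mm is missing"
        )
    return (
        lesion.stenosis_pct >= MIN_STENOSIS_PCT
        and lesion.vessel_diameter_mm > MIN_VESSEL_DIAMETER_MM
    )


def lesion_score(weight: float, occlusive: bool) -> float:
    """Weight x stenosis multiplier (2.0 non-occlusive, 5.0 occlusive)."""
    if not weight > 0:
        raise ValidationError(f"segment weight must be > 0, got {weight}")
    return weight * (OCCLUSIVE_MULTIPLIER if occlusive else NON_OCCLUSIVE_MULTIPLIER)


def catlet_score(
    patient: PatientRecord,
    table: SegmentWeightTable,
    occlusion_mode: OcclusionMode = "force_non_occlusive",
) -> float:
    """Sum of per-lesion scores over the patient's eligible lesions.

    ``occlusion_mode="force_non_occlusive"`` (default) scores every lesion
    with the non-occlusive multiplier — the convention for occlusions that
    were wired/ballooned open for evaluation; ``"as_recorded"`` honours each
    lesion's occlusive flag. Ineligible lesions are excluded with a logged
    warning rather than an error, since registry data contain sub-threshold
    lesions. A patient with no eligible lesion scores 0.
    """
    total = 0.0
    for lesion in patient.lesions:
        if not eligible_lesion(lesion):
            logger.warning(
                "patient %s: lesion in %s (stenosis %.1f%%, diameter %s mm) "
                "does not meet the inclusion rule; excluded from scoring",
                patient.patient_id, lesion.segment_id,
                lesion.stenosis_pct, lesion.vessel_diameter_mm,
            )
            continue
        weight = table.weight(patient.pattern, lesion.segment_id)
        occlusive = False if occlusion_mode == "force_non_occlusive" else lesion.occlusive
        total += lesion_score(weight, occlusive)
    return total


def acef_score(
    age: float,
    lvef: float,
    creatinine: float,
    unit: CreatinineUnit | str = CreatinineUnit.UMOL_PER_L,
) -> float:
    """ACEF I: age/LVEF, plus 1 if creatinine >= 2 mg/dL (171.68 umol/L)."""
    if not age > 0:
        raise ValidationError(f"age must be > 0, got {age}")
    if not 0 < lvef <= 100:
        raise ValidationError(f"lvef must be in (0, 100], got {lvef}")
    if not creatinine > 0:
        raise ValidationError(f"creatinine must be > 0, got {creatinine}")
    try:
        unit = CreatinineUnit(unit)
    except ValueError:
        raise ValidationError(
            f"unknown creatinine unit {unit!r}; legal units: "
            f"{[u.value for u in CreatinineUnit]}"
        ) from None
    mg_dl = creatinine / UMOL_PER_MG_DL if unit is CreatinineUnit.UMOL_PER_L else creatinine
    return age / lvef + (1.0 if mg_dl >= CREATININE_THRESHOLD_MG_DL else 0.0)


def clinical_catlet_score(cs: float, acef: float) -> float:
    """CCS = CS x ACEF I."""
    if cs < 0:
        raise ValidationError(f"CatLet score must be >= 0, got {cs}")
    if not acef > 0:
        raise ValidationError(f"ACEF score must be > 0, got {acef}")
    return cs * acef


def score_patient(
    patient: PatientRecord,
    table: SegmentWeightTable,
    occlusion_mode: OcclusionMode = "force_non_occlusive",
) -> ScoreSet:
    """Compute the full ScoreSet (CS, ACEF I, CCS) for one patient."""
    cs = catlet_score(patient, table, occlusion_mode)
    acef = acef_score(patient.age, patient.lvef, patient.creatinine, patient.creatinine_unit)
    return ScoreSet(catlet_score=cs, acef=acef, clinical_catlet_score=clinical_catlet_score(cs, acef))
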