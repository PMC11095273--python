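"""Published summary statistics of the >12h-presentation AMI validation
registry (n = 1018, 4-year follow-up).

The patient-level registry is not publicly deposited, so these printed
summaries serve two roles only: (1) default targets for the synthetic
cohort generator, so simulated cohorts carry the registry's statistical
structure, and (2) reference templates when laying out reports. They are
never asserted as the output of any computation on synthetic data —
patient-level quantities (AUCs, hazard ratios, NRIs) are not recoverable
from summary statistics alone.
"""

from __future__ import annotations

from types import MappingProxyType

N_PATIENTS = 1018

#: 4-year event counts by endpoint
EVENT_COUNTS = MappingProxyType({
    "mace": 234,
    "all_cause_death": 130,
    "cardiac_death": 93,
    "myocardial_infarction": 133,
    "revascularization": 131,
})

MACE_EVENT_RATE = EVENT_COUNTS["mace"] / N_PATIENTS  # 0.2299, printed as 23.0%

#: crude per-SD hazard ratios (CatLet score / Clinical CatLet score)
HR_PER_SD_CS = MappingProxyType({
    "mace": 1.90,
    "all_cause_death": 1.90,
    "cardiac_death": 2.17,
    "myocardial_infarction": 1.88,
    "revascularization": 1.70,
})
HR_PER_SD_CCS = MappingProxyType({
    "mace": 1.98,
    "all_cause_death": 2.22,
    "cardiac_death": 2.36,
    "myocardial_infarction": 2.07,
    "revascularization": 1.55,
})

#: standardisation SDs used for the per-SD hazard ratios
SD_CS = 8.1
SD_CCS = 15.6

#: CatLet score distribution (right-skewed)
CS_MEAN, CS_SD = 16.38, 8.10
CS_MEDIAN, CS_IQR = 14.0, (10.0, 21.0)
CS_RANGE = (2.0, 47.5)

#: Clinical CatLet score distribution
CCS_MEAN, CCS_SD = 22.36, 15.65
CCS_MEDIAN, CCS_IQR = 17.73, (11.37, 29.11)

#: published tertile bounds (low <= b1 < mid <= b2 < top)
CS_TERTILE_BOUNDS = (12.0, 18.0)
CCS_TERTILE_BOUNDS = (13.0, 24.0)

#: lesions per patient
LESIONS_PER_PATIENT_MEAN, LESIONS_PER_PATIENT_SD = 1.70, 0.94

#: applied (rounded) risk-category cutoffs: half / one / two times the rate
RISK_CUTOFFS = (0.10, 0.20, 0.40)

#: coronary anatomy frequencies (counts over the full cohort)
LAD_LENGTH_COUNTS = MappingProxyType({"average": 600, "long": 287, "short": 131})
DIAGONAL_SIZE_COUNTS = MappingProxyType({"intermediate": 720, "large": 203, "small": 95})
DOMINANCE_COUNTS = MappingProxyType({
    "average_rca": 336,
    "large_rca": 256,
    "small_rca": 256,
    "pda_only": 64,
    "pda_zero": 52,
    "super_rca": 54,
})

#: apparent AUCs (model comparison), reference template only
AUC_CS = MappingProxyType({
    "mace": 0.72, "all_cause_death": 0.68, "cardiac_death": 0.73,
    "myocardial_infarction": 0.69, "revascularization": 0.66,
})
AUC_CCS = MappingProxyType({
    "mace": 0.75, "all_cause_death": 0.78, "cardiac_death": 0.83,
    "myocardial_infarction": 0.75, "revascularization": 0.63,
})
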