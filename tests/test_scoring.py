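import logging

import pytest
from hypothesis import given, settings, strategies as st

from catlet.errors import ValidationError
from catlet.patterns import resolve_pattern
from catlet.scoring import (
    CreatinineUnit,
    LesionRecord,
    PatientRecord,
    acef_score,
    catlet_score,
    clinical_catlet_score,
    eligible_lesion,
    lesion_score,
    score_patient,
)

from conftest import toy_table

PATTERN = resolve_pattern("average", "intermediate", "average_rca")


def make_patient(lesions, **overrides):
    defaults = dict(
        patient_id="P1",
        age=65.0,
        sex="male",
        lvef=50.0,
        creatinine=71.0,
        creatinine_unit=CreatinineUnit.UMOL_PER_L,
        pattern=PATTERN,
        lesions=tuple(lesions),
    )
    defaults.update(overrides)
    return PatientRecord(**defaults)


def lesion(segment="A", stenosis=80.0, occlusive=False, diameter=3.0):
    return LesionRecord(
        segment_id=segment,
        stenosis_pct=stenosis,
        occlusive=occlusive,
        vessel_diameter_mm=diameter,
    )


class TestEligibility:
    @pytest.mark.parametrize(
        "stenosis, diameter, expected",
        [
            (50.0, 2.0, True),    # inclusion rule boundary: >=50% qualifies
            (49.9, 3.0, False),
            (80.0, 1.5, False),   # vessel diameter strictly > 1.5 mm
            (100.0, 1.51, True),
        ],
    )
    def test_inclusion_rule_boundaries(self, stenosis, diameter, expected):
        les = LesionRecord(
            segment_id="A",
            stenosis_pct=stenosis,
            occlusive=stenosis == 100.0,
            vessel_diameter_mm=diameter,
        )
        assert eligible_lesion(les) is expected

    def test_missing_diameter_is_named_in_error(self):
        les = LesionRecord(segment_id="A", stenosis_pct=60.0)
        with pytest.raises(ValidationError, match="vessel_diameter_mm"):
            eligible_lesion(les)

    def test_occlusive_requires_total_stenosis(self):
        with pytest.raises(ValidationError, match="100"):
            LesionRecord(segment_id="A", stenosis_pct=90.0, occlusive=True)


class TestLesionScore:
    def test_multipliers(self):
        assert lesion_score(2.5, occlusive=True) == pytest.approx(12.5)
        assert lesion_score(2.5, occlusive=False) == pytest.approx(5.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_occlusive_to_nonocclusive_ratio_is_5_over_2(self, w):
        assert lesion_score(w, True) / lesion_score(w, False) == pytest.approx(2.5)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError):
            lesion_score(0.0, False)


class TestCatletScore:
    table = toy_table({"A": 3.0, "B": 4.0, "C": 1.0})

    def test_no_eligible_lesions_scores_zero(self, caplog):
        patient = make_patient([lesion(stenosis=40.0)])
        with caplog.at_level(logging.WARNING, logger="catlet.scoring"):
            assert catlet_score(patient, self.table) == 0.0
        assert "does not meet the inclusion rule" in caplog.text

    def test_sum_of_nonocclusive_lesions(self):
        patient = make_patient([lesion("A"), lesion("B")])
        assert catlet_score(patient, self.table) == pytest.approx(14.0)  # 3*2 + 4*2

    def test_occlusion_switch_adds_three_weights(self):
        base = make_patient([lesion("A"), lesion("B")])
        occl = make_patient(
            [lesion("A", stenosis=100.0, occlusive=True), lesion("B")]
        )
        as_rec = catlet_score(occl, self.table, "as_recorded")
        assert as_rec - catlet_score(base, self.table, "as_recorded") == pytest.approx(
            3 * 3.0
        )
        # default mode scores non-occlusive status, so the switch is neutral
        assert catlet_score(occl, self.table) == catlet_score(base, self.table)
        assert catlet_score(occl, self.table) <= as_rec

    def test_monotone_in_lesion_set(self):
        small = make_patient([lesion("A")])
        large = make_patient([lesion("A"), lesion("C")])
        assert catlet_score(large, self.table) >= catlet_score(small, self.table)


class TestAcef:
    @pytest.mark.parametrize(
        "age, lvef, creat, unit, expected",
        [
            (65, 50, 71.0, "umol_per_L", 1.30),
            (60, 50, 2.5, "mg_per_dL", 2.20),
            (60, 50, 176.8, "umol_per_L", 2.20),   # 176.8/88.4 = 2.0, inclusive
            (60, 50, 176.7, "umol_per_L", 1.20),
        ],
    )
    def test_formula_and_renal_threshold(self, age, lvef, creat, unit, expected):
        assert acef_score(age, lvef, creat, unit) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            acef_score(65, 0, 71)
        with pytest.raises(ValidationError, match="unit"):
            acef_score(65, 50, 71, "mmol_per_L")

    @given(
        age=st.floats(min_value=20, max_value=95),
        bump=st.floats(min_value=0.1, max_value=20),
        lvef=st.floats(min_value=15, max_value=80),
    )
    @settings(max_examples=50)
    def test_monotone_in_age_and_lvef(self, age, bump, lvef):
        assert acef_score(age + bump, lvef, 71) > acef_score(age, lvef, 71)
        assert acef_score(age, lvef + bump, 71) < acef_score(age, lvef, 71)


class TestClinicalCatlet:
    def test_product_and_identities(self):
        assert clinical_catlet_score(14, 1.30) == pytest.approx(18.2)
        assert clinical_catlet_score(0, 2.0) == 0.0
        assert clinical_catlet_score(23.5, 1.0) == 23.5

    def test_ccs_at_least_cs_when_acef_at_least_one(self):
        assert clinical_catlet_score(10, 1.2) >= 10

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            clinical_catlet_score(-1, 1.0)
        with pytest.raises(ValidationError):
            clinical_catlet_score(1, 0.0)


def test_score_patient_composes_all_three():
    table = toy_table({"A": 3.0, "B": 4.0})
    patient = make_patient([lesion("A"), lesion("B")], age=65, lvef=50)
    s = score_patient(patient, table)
    assert s.catlet_score == pytest.approx(14.0)
    assert s.acef == pytest.approx(1.30)
    assert s.clinical_catlet_score == pytest.approx(s.catlet_score * s.acef)
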