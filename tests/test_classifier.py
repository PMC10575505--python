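"""Justification lookup, Charlson scoring and the five-category decision table."""

import itertools

import pandas as pd
import pytest

from capqual.classifier import (
    JustificationProfile,
    build_justifications,
    classify,
    compute_charlson,
)
from capqual.config import CodeConfig, ConfigError, DEFAULT_CHARLSON_WEIGHTS
from capqual.guidelines import ConcordanceResult, assess_concordance
from helpers_oracles import classify_oracle

EPOCH = pd.Timestamp("2014-01-01")


def _visit(patient, day, code, system="ICD9"):
    return {"patient_id": patient, "service_date":
            (EPOCH + pd.Timedelta(days=day)).strftime("%Y-%m-%d"),
            "diagnostic_code": code, "code_system": system, "provider_type": "GP"}


def _disp(patient, day, atc):
    return {"record_id": 1, "patient_id": patient, "dispense_date":
            (EPOCH + pd.Timedelta(days=day)).strftime("%Y-%m-%d"),
            "agent": "x", "atc_code": atc, "strength_mg": 5.0,
            "quantity": 30, "days_supply": 30, "form": "tablet"}


def _adm(patient, day, code):
    return {"patient_id": patient, "admission_date":
            (EPOCH + pd.Timedelta(days=day)).strftime("%Y-%m-%d"),
            "discharge_date": (EPOCH + pd.Timedelta(days=day + 3)).strftime("%Y-%m-%d"),
            "diagnosis_codes": code}


_EMPTY_V = pd.DataFrame(columns=["patient_id", "service_date", "diagnostic_code",
                                 "code_system", "provider_type"])
_EMPTY_D = pd.DataFrame(columns=["record_id", "patient_id", "dispense_date",
                                 "agent", "atc_code", "strength_mg", "quantity",
                                 "days_supply", "form"])
_EMPTY_A = pd.DataFrame(columns=["patient_id", "admission_date", "discharge_date",
                                 "diagnosis_codes"])

INDEX = EPOCH + pd.Timedelta(days=400)


class TestBuildJustifications:
    def test_no_prior_records_means_no_justification(self):
        profile = build_justifications("P1", INDEX, _EMPTY_V, _EMPTY_A, _EMPTY_D)
        assert not any(profile.conditions.values())
        assert profile.charlson_score == 0
        assert not profile.has_any_justification

    def test_copd_visit_inside_lookback_sets_flag(self):
        visits = pd.DataFrame([_visit("P1", 300, "491")])  # 100 days before index
        profile = build_justifications("P1", INDEX, visits, _EMPTY_A, _EMPTY_D)
        assert profile.conditions["copd"]
        assert profile.has_any_justification

    def test_record_outside_lookback_ignored(self):
        visits = pd.DataFrame([_visit("P1", 10, "491")])  # 390 days before index
        profile = build_justifications("P1", INDEX, visits, _EMPTY_A, _EMPTY_D)
        assert not profile.conditions["copd"]

    def test_record_after_index_ignored(self):
        visits = pd.DataFrame([_visit("P1", 410, "491")])
        profile = build_justifications("P1", INDEX, visits, _EMPTY_A, _EMPTY_D)
        assert not profile.conditions["copd"]

    def test_immunosuppressant_dispensation_sets_medication_flag(self):
        disp = pd.DataFrame([_disp("P1", 350, "H02AB06")])
        profile = build_justifications("P1", INDEX, _EMPTY_V, _EMPTY_A, disp)
        assert profile.immunosuppressive_meds
        assert profile.has_any_justification

    def test_hospital_icd10_diagnosis_sets_condition_flag(self):
        adm = pd.DataFrame([_adm("P1", 320, "N18;I10")])
        profile = build_justifications("P1", INDEX, _EMPTY_V, adm, _EMPTY_D)
        assert profile.conditions["ckd"] and profile.conditions["hypertension"]

    def test_other_patients_records_do_not_leak(self):
        visits = pd.DataFrame([_visit("P2", 300, "491")])
        profile = build_justifications("P1", INDEX, visits, _EMPTY_A, _EMPTY_D)
        assert not profile.has_any_justification

    def test_missing_condition_weight_is_configuration_error(self):
        config = CodeConfig()
        config.condition_codes["gout"] = {"ICD9": ["274"], "ICD10": ["M10"]}
        with pytest.raises(ConfigError, match="gout"):
            build_justifications("P1", INDEX, _EMPTY_V, _EMPTY_A, _EMPTY_D, config)


class TestCharlson:
    def test_empty(self):
        assert compute_charlson({}, DEFAULT_CHARLSON_WEIGHTS) == 0

    def test_mi_diabetes_cancer_sums_to_four(self):
        flags = {"mi": True, "diabetes": True, "cancer": True}
        assert compute_charlson(flags, DEFAULT_CHARLSON_WEIGHTS) == 4

    def test_all_conditions_equal_total_weight(self):
        flags = {c: True for c in DEFAULT_CHARLSON_WEIGHTS}
        assert compute_charlson(flags, DEFAULT_CHARLSON_WEIGHTS) == sum(
            DEFAULT_CHARLSON_WEIGHTS.values()
        )

    def test_unknown_condition_raises(self):
        with pytest.raises(ConfigError):
            compute_charlson({"gout": True}, DEFAULT_CHARLSON_WEIGHTS)

    def test_charlson_of_three_is_a_justification_on_its_own(self):
        profile = JustificationProfile(charlson_score=3, charlson_threshold=3)
        assert profile.has_any_justification
        profile = JustificationProfile(charlson_score=2, charlson_threshold=3)
        assert not profile.has_any_justification


def _profile(justified: bool, ckd: bool) -> JustificationProfile:
    return JustificationProfile(conditions={"copd": justified, "ckd": ckd})


class TestDecisionTable:
    def test_fully_concordant_first_line_is_guideline_adherent(self, rules):
        conc = assess_concordance("amoxicillin", "J01CA04", 3000, 5, rules)
        out = classify({"episode_id": "e"}, conc, _profile(False, False))
        assert out.category == "guideline_adherent"

    def test_opposing_deviation_goes_to_undertreatment(self, rules):
        conc = assess_concordance("amoxicillin", "J01CA04", 1500, 10, rules)
        out = classify({"episode_id": "e"}, conc, _profile(False, False))
        assert out.category == "undertreatment"
        assert not out.reclassified_from_undertreatment

    def test_ckd_reclassifies_undertreatment_to_clinically_appropriate(self, rules):
        conc = assess_concordance("amoxicillin", "J01CA04", 1500, 10, rules)
        out = classify({"episode_id": "e"}, conc, _profile(False, True))
        assert out.category == "clinically_appropriate"
        assert out.reclassified_from_undertreatment
        assert "ckd_reclassification" in out.reason_trace

    def test_ckd_does_not_touch_excess_prescribing(self, rules):
        conc = assess_concordance("amoxicillin", "J01CA04", 2500, 10, rules)
        out = classify({"episode_id": "e"}, conc, _profile(False, True))
        assert out.category == "effective_but_unnecessary"

    def test_non_first_line_splits_on_justification(self, rules):
        conc = assess_concordance("azithromycin", "J01FA10", 500, 5, rules)
        assert classify({"episode_id": "e"}, conc,
                        _profile(True, False)).category == "clinically_appropriate"
        assert classify({"episode_id": "e"}, conc,
                        _profile(False, False)).category == "not_recommended"

    def test_unknown_agent_treated_as_non_first_line(self, rules):
        conc = assess_concordance("mystery", "X00AB12", 10, 3, rules)
        out = classify({"episode_id": "e"}, conc, _profile(False, False))
        assert out.category == "not_recommended"
        assert "unknown_agent_as_non_first_line" in out.reason_trace

    def test_full_grid_matches_brute_force_oracle(self):
        """All 72 cells of agent-class x dose x duration x justification x CKD."""
        directions = ("below", "within", "above")
        cells = 0
        for first_line, dose_dir, dur_dir, justified, ckd in itertools.product(
            (True, False), directions, directions, (True, False), (True, False)
        ):
            if first_line:
                conc = ConcordanceResult(True, dose_dir, dur_dir)
            else:
                conc = ConcordanceResult(False)
            got = classify({"episode_id": "e"}, conc, _profile(justified, ckd))
            expected_cat, expected_reclass = classify_oracle(
                first_line, dose_dir, dur_dir, justified, ckd
            )
            assert got.category == expected_cat, (first_line, dose_dir, dur_dir,
                                                  justified, ckd)
            assert got.reclassified_from_undertreatment == expected_reclass
            cells += 1
        assert cells == 72

    def test_exactly_one_category_always_assigned(self):
        categories = {"guideline_adherent", "clinically_appropriate",
                      "effective_but_unnecessary", "undertreatment",
                      "not_recommended"}
        for first_line, dose_dir, dur_dir, justified, ckd in itertools.product(
            (True, False), ("below", "within", "above"), ("below", "within", "above"),
            (True, False), (True, False)
        ):
            conc = (ConcordanceResult(True, dose_dir, dur_dir) if first_line
                    else ConcordanceResult(False))
            out = classify({"episode_id": "e"}, conc, _profile(justified, ckd))
            assert out.category in categories
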