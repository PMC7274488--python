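"""Phenotyping rule engine: case definitions, exclusions, partition properties."""

import pandas as pd
import pytest

from thyromr.cohort_builder import (
    apply_dual_diagnosis_exclusion,
    assignment_counts,
    build_cohort,
    define_benign_cases,
    define_t2dm_status,
    define_thyroid_cancer_cases,
    select_controls,
    sensitivity_exclude_thyroid_dysfunction,
    validate_diagnoses,
)


def _status(assignment: pd.DataFrame, pid: str) -> tuple[str, str]:
    row = assignment.set_index("participant_id").loc[pid]
    return row["status"], row["exclusion_reason"]


class TestCancerCases:
    def test_papillary_is_case_medullary_is_excluded(self, registry_diagnoses):
        out = define_thyroid_cancer_cases(registry_diagnoses)
        assert _status(out, "P01") == ("cancer_case", "")
        assert _status(out, "P02") == ("excluded", "histology")
        assert _status(out, "P15") == ("excluded", "histology")
        assert _status(out, "P19") == ("excluded", "histology")

    def test_recurrence_collapses_to_first_diagnosis(self, registry_diagnoses):
        out = define_thyroid_cancer_cases(registry_diagnoses).set_index(
            "participant_id"
        )
        assert out.loc["P03", "status"] == "cancer_case"
        assert out.loc["P03", "index_date"] == pd.Timestamp("2008-03-01")

    def test_mixed_histology_keeps_eligible_record(self, registry_diagnoses):
        out = define_thyroid_cancer_cases(registry_diagnoses).set_index(
            "participant_id"
        )
        assert out.loc["P16", "status"] == "cancer_case"
        assert out.loc["P16", "index_date"] == pd.Timestamp("2011-02-01")

    def test_malformed_code_rejected(self):
        bad = pd.DataFrame(
            {
                "participant_id": ["X1"],
                "icd10_code": ["C7"],
                "diagnosis_date": [pd.Timestamp("2010-01-01")],
                "histology_class": ["papillary"],
                "toxic_flag": [False],
            }
        )
        with pytest.raises(ValueError, match="X1"):
            validate_diagnoses(bad)


class TestBenignCases:
    def test_non_toxic_case_toxic_excluded(self, registry_diagnoses):
        out = define_benign_cases(registry_diagnoses)
        assert _status(out, "P04") == ("benign_case", "")
        assert _status(out, "P05") == ("excluded", "toxic")

    def test_toxic_then_nontoxic_indexes_at_nontoxic(self, registry_diagnoses):
        out = define_benign_cases(registry_diagnoses).set_index("participant_id")
        assert out.loc["P17", "status"] == "benign_case"
        assert out.loc["P17", "index_date"] == pd.Timestamp("2010-11-01")


class TestDualDiagnosisWindow:
    def test_close_dates_excluded_far_dates_retained(self, registry_diagnoses):
        cancer = define_thyroid_cancer_cases(registry_diagnoses)
        benign = define_benign_cases(registry_diagnoses)
        cancer, benign = apply_dual_diagnosis_exclusion(cancer, benign, 12)
        assert _status(cancer, "P07") == ("excluded", "diagnostic_uncertainty")
        assert _status(benign, "P07") == ("excluded", "diagnostic_uncertainty")
        assert _status(cancer, "P08") == ("cancer_case", "")
        assert _status(benign, "P08") == ("benign_case", "")

    def test_zero_window_is_noop(self, registry_diagnoses):
        cancer = define_thyroid_cancer_cases(registry_diagnoses)
        benign = define_benign_cases(registry_diagnoses)
        c2, b2 = apply_dual_diagnosis_exclusion(cancer, benign, 0)
        assert (c2["status"] == cancer["status"]).all()
        assert (b2["status"] == benign["status"]).all()

    @pytest.mark.parametrize("windows", [(0, 6, 12, 24, 48)])
    def test_case_count_monotone_in_window(self, registry_diagnoses, windows):
        counts = []
        for w in windows:
            cancer = define_thyroid_cancer_cases(registry_diagnoses)
            benign = define_benign_cases(registry_diagnoses)
            cancer, benign = apply_dual_diagnosis_exclusion(cancer, benign, w)
            counts.append(
                (
                    (cancer["status"] == "cancer_case").sum(),
                    (benign["status"] == "benign_case").sum(),
                )
            )
        for earlier, later in zip(counts, counts[1:]):
            assert later[0] <= earlier[0] and later[1] <= earlier[1]


class TestT2DM:
    def test_questionnaire_criteria(self, registry_participants):
        t2dm = define_t2dm_status(registry_participants)
        assert not t2dm["P11"]  # diagnosed under 35
        assert not t2dm["P12"]  # insulin in first year
        assert t2dm["P13"]  # age 50, no insulin, 5 years before enrollment
        assert not t2dm["P14"]  # missing insulin field fails conservatively
        assert not t2dm["P18"]  # diagnosed within a year of enrollment
        assert not t2dm["P06"]  # no self-report

    def test_idempotent(self, registry_participants):
        a = define_t2dm_status(registry_participants)
        b = define_t2dm_status(registry_participants)
        assert (a == b).all()


class TestControlsAndPartition:
    def test_other_cancer_blocks_cancer_control_only(
        self, registry_participants, registry_diagnoses
    ):
        result = build_cohort(registry_participants, registry_diagnoses)
        assert _status(result["cancer"], "P09") == ("excluded", "cancer_history")
        assert _status(result["benign"], "P09") == ("benign_control", "")

    def test_clean_participant_is_control_in_both(
        self, registry_participants, registry_diagnoses
    ):
        result = build_cohort(registry_participants, registry_diagnoses)
        for pid in ("P06", "P20"):
            assert _status(result["cancer"], pid) == ("cancer_control", "")
            assert _status(result["benign"], pid) == ("benign_control", "")

    def test_toxic_nodule_neither_case_nor_control(
        self, registry_participants, registry_diagnoses
    ):
        result = build_cohort(registry_participants, registry_diagnoses)
        status, reason = _status(result["benign"], "P05")
        assert status == "excluded" and reason == "toxic"

    def test_partition_every_participant_exactly_once(
        self, registry_participants, registry_diagnoses
    ):
        result = build_cohort(registry_participants, registry_diagnoses)
        for outcome in ("cancer", "benign"):
            table = result[outcome]
            assert len(table) == len(registry_participants)
            assert table["participant_id"].is_unique
            assert set(table["status"]) <= {
                f"{outcome}_case",
                f"{outcome}_control",
                "excluded",
            }
            excluded = table[table["status"] == "excluded"]
            assert (excluded["exclusion_reason"] != "").all()

    def test_idempotent_build(self, registry_participants, registry_diagnoses):
        a = build_cohort(registry_participants, registry_diagnoses)
        b = build_cohort(registry_participants, registry_diagnoses)
        for key in ("cancer", "benign"):
            pd.testing.assert_frame_equal(a[key], b[key])


class TestSensitivityExclusion:
    def test_dysfunction_carrier_removed(
        self, registry_participants, registry_diagnoses
    ):
        assignment = build_cohort(registry_participants, registry_diagnoses)["benign"]
        updated = sensitivity_exclude_thyroid_dysfunction(
            assignment, registry_diagnoses
        )
        assert _status(updated, "P10") == ("excluded", "thyroid_dysfunction")
        # everyone else untouched
        untouched = updated[updated["participant_id"] != "P10"]
        original = assignment[assignment["participant_id"] != "P10"]
        assert (untouched["status"].to_numpy() == original["status"].to_numpy()).all()

    def test_empty_code_list_warns_and_noop(
        self, registry_participants, registry_diagnoses
    ):
        assignment = build_cohort(registry_participants, registry_diagnoses)["benign"]
        with pytest.warns(UserWarning, match="no-op"):
            updated = sensitivity_exclude_thyroid_dysfunction(
                assignment, registry_diagnoses, code_prefixes=()
            )
        pd.testing.assert_frame_equal(updated, assignment)

    def test_counts_summary(self, registry_participants, registry_diagnoses):
        table = build_cohort(registry_participants, registry_diagnoses)["benign"]
        counts = assignment_counts(table)
        assert counts["benign_case"] == (table["status"] == "benign_case").sum()
        assert sum(counts.values()) == len(table)
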