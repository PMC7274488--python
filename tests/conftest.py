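"""Shared fixtures: a 20-participant registry fixture covering every phenotyping rule."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def _participants() -> pd.DataFrame:
    ids = [f"P{i:02d}" for i in range(1, 21)]
    df = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    df["sex"] = ["F", "M"] * 10
    df["age_at_recruitment"] = 55
    df["enrollment_date"] = pd.Timestamp("2008-01-01")
    df["self_report_diabetes"] = False
    df["age_at_diabetes_diagnosis"] = np.nan
    df["insulin_within_first_year"] = pd.array([pd.NA] * 20, dtype="boolean")

    # questionnaire diabetes scenarios
    df.loc["P11", ["self_report_diabetes", "age_at_diabetes_diagnosis"]] = [True, 30]
    df.loc["P11", "insulin_within_first_year"] = False
    df.loc["P12", ["self_report_diabetes", "age_at_diabetes_diagnosis"]] = [True, 50]
    df.loc["P12", "insulin_within_first_year"] = True
    df.loc["P13", ["self_report_diabetes", "age_at_diabetes_diagnosis"]] = [True, 50]
    df.loc["P13", "insulin_within_first_year"] = False
    df.loc["P14", ["self_report_diabetes", "age_at_diabetes_diagnosis"]] = [True, 50]
    # P14 insulin left missing
    df.loc["P18", ["self_report_diabetes", "age_at_diabetes_diagnosis"]] = [True, 55]
    df.loc["P18", "insulin_within_first_year"] = False  # diagnosed at enrollment age

    # minimal covariates so regression-facing code can run on the fixture
    df["smoking"] = "never"
    df["alcohol_units_week"] = 5.0
    df["townsend"] = 0.0
    df["bmi"] = 27.0
    return df


def _diagnoses() -> pd.DataFrame:
    rows = [
        # (pid, code, date, histology, toxic)
        ("P01", "C73", "2010-01-15", "papillary", False),
        ("P02", "C73", "2010-02-01", "medullary", False),
        ("P03", "C73", "2008-03-01", "papillary", False),
        ("P03", "C73", "2010-05-01", "papillary", False),
        ("P04", "D34", "2011-07-01", "not_applicable", False),
        ("P05", "D34", "2011-08-01", "not_applicable", True),
        # P06: no records (clean control)
        ("P07", "C73", "2009-06-01", "papillary", False),
        ("P07", "D34", "2009-01-01", "not_applicable", False),
        ("P08", "C73", "2012-01-01", "follicular", False),
        ("P08", "D34", "2009-01-01", "not_applicable", False),
        ("P09", "C50", "2010-03-01", "not_applicable", False),
        ("P10", "E03", "2009-09-01", "not_applicable", False),
        ("P15", "C73", "2010-04-01", "anaplastic", False),
        ("P16", "C73", "2011-02-01", "papillary", False),
        ("P16", "C73", "2010-06-01", "medullary", False),
        ("P17", "D34", "2009-05-01", "not_applicable", True),
        ("P17", "D34", "2010-11-01", "not_applicable", False),
        ("P19", "C73", "2010-08-01", "unspecified", False),
        # P20: no records (clean control)
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "icd10_code",
            "diagnosis_date",
            "histology_class",
            "toxic_flag",
        ],
    )
    df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"])
    return df


@pytest.fixture(scope="session")
def registry_participants() -> pd.DataFrame:
    return _participants()


@pytest.fixture(scope="session")
def registry_diagnoses() -> pd.DataFrame:
    return _diagnoses()
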