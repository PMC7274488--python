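"""Registry- and questionnaire-based case/control definitions.

Implements, as an auditable rule engine over long-format diagnosis records:

* differentiated thyroid-cancer cases: ICD-10 ``C73`` restricted to papillary
  or follicular histology (medullary, anaplastic, lymphoma, and unspecified
  subtypes have distinct aetiology and are excluded), indexed at the first
  eligible diagnosis so recurrences and duplicate records never double-count;
* benign nodular thyroid disease cases: ICD-10 ``D34`` with toxic nodules
  excluded, again indexed at first diagnosis;
* a dual-diagnosis window: participants with both diagnoses within 12 months
  are removed from both analyses as diagnostically uncertain;
* type 2 diabetes status from self-report, excluding likely type 1 diabetes
  (diagnosis under age 35, insulin in the first year, diagnosis within a
  year of enrollment);
* separate control groups per outcome: cancer controls have no history of
  any cancer, benign controls no history of nodular thyroid disease;
* a sensitivity switch removing participants with thyroid dysfunction
  (hypo-/hyperthyroidism, ICD-10 E03/E05 by default).

Every participant ends up in exactly one of case / control / excluded per
outcome, and every exclusion carries a reason string.
"""

from __future__ import annotations

import logging
import re
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Za-z]{1,2})?$")

ELIGIBLE_HISTOLOGY = frozenset({"papillary", "follicular"})
HISTOLOGY_CLASSES = frozenset(
    {
        "papillary",
        "follicular",
        "medullary",
        "anaplastic",
        "lymphoma",
        "unspecified",
        "not_applicable",
    }
)

#: default thyroid-dysfunction code prefixes (hypothyroidism, thyrotoxicosis)
DEFAULT_DYSFUNCTION_CODES = ("E03", "E05")

DAYS_PER_MONTH = 365.25 / 12.0

ASSIGNMENT_COLUMNS = ["participant_id", "status", "exclusion_reason", "index_date"]


def validate_diagnoses(diagnoses: pd.DataFrame) -> None:
    """Validate registry rows; raises naming the offending records."""
    required = {"participant_id", "icd10_code", "diagnosis_date"}
    missing = required - set(diagnoses.columns)
    if missing:
        raise ValueError(f"diagnosis table missing columns: {sorted(missing)}")
    if len(diagnoses) == 0:
        return
    codes = diagnoses["icd10_code"].astype(str)
    bad = ~codes.str.match(ICD10_PATTERN)
    if bad.any():
        offenders = diagnoses.loc[bad, ["participant_id", "icd10_code"]]
        raise ValueError(
            "malformed ICD-10 codes: "
            + "; ".join(
                f"{r.participant_id}={r.icd10_code!r}" for r in offenders.itertuples()
            )
        )
    if "histology_class" in diagnoses.columns:
        unknown = set(diagnoses["histology_class"].dropna()) - HISTOLOGY_CLASSES
        if unknown:
            raise ValueError(f"unknown histology classes: {sorted(unknown)}")


def _first_eligible(
    diag: pd.DataFrame, eligible_mask: pd.Series, exclusion_reason: str
) -> pd.DataFrame:
    """Per participant: case with earliest eligible date, else excluded."""
    eligible = diag[eligible_mask]
    index_dates = eligible.groupby("participant_id")["diagnosis_date"].min()
    all_ids = diag["participant_id"].unique()
    excluded_ids = np.setdiff1d(all_ids, index_dates.index.to_numpy())
    out = pd.DataFrame(
        {
            "participant_id": np.concatenate([index_dates.index, excluded_ids]),
            "status": ["case"] * len(index_dates) + ["excluded"] * len(excluded_ids),
            "exclusion_reason": [""] * len(index_dates)
            + [exclusion_reason] * len(excluded_ids),
            "index_date": list(index_dates.to_numpy())
            + [pd.NaT] * len(excluded_ids),
        }
    )
    out["index_date"] = pd.to_datetime(out["index_date"])
    return out.sort_values("participant_id").reset_index(drop=True)


def define_thyroid_cancer_cases(diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Cancer cases: >=1 C73 record with papillary/follicular histology.

    Participants whose only C73 records carry an excluded histology
    (medullary, anaplastic, lymphoma, unspecified) are excluded with reason
    ``histology``. The earliest eligible diagnosis date becomes the index
    date, so duplicated records and recurrences collapse to one case.
    """
    validate_diagnoses(diagnoses)
    c73 = diagnoses[diagnoses["icd10_code"].astype(str).str.startswith("C73")].copy()
    if len(c73) == 0:
        return pd.DataFrame(columns=ASSIGNMENT_COLUMNS)
    eligible = c73["histology_class"].isin(ELIGIBLE_HISTOLOGY)
    out = _first_eligible(c73, eligible, "histology")
    out.loc[out["status"] == "case", "status"] = "cancer_case"
    return out


def define_benign_cases(diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Benign nodular disease cases: >=1 non-toxic D34 record.

    Participants with only toxic-nodule D34 records are excluded with reason
    ``toxic``; the earliest non-toxic date is the index date.
    """
    validate_diagnoses(diagnoses)
    d34 = diagnoses[diagnoses["icd10_code"].astype(str).str.startswith("D34")].copy()
    if len(d34) == 0:
        return pd.DataFrame(columns=ASSIGNMENT_COLUMNS)
    eligible = ~d34["toxic_flag"].astype(bool)
    out = _first_eligible(d34, eligible, "toxic")
    out.loc[out["status"] == "case", "status"] = "benign_case"
    return out


def apply_dual_diagnosis_exclusion(
    cancer_assign: pd.DataFrame,
    benign_assign: pd.DataFrame,
    window_months: float = 12,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude participants with both diagnoses within ``window_months``.

    Index dates strictly closer than the window flag diagnostic uncertainty
    (a nodule worked up and found malignant, or vice versa) and the
    participant leaves both analyses; pairs at or beyond the window keep both
    statuses — a prior benign nodule is a real antecedent of cancer, not an
    artefact. ``window_months=0`` therefore excludes nobody.
    """
    if window_months < 0:
        raise ValueError("window_months must be >= 0")
    cancer = cancer_assign.copy()
    benign = benign_assign.copy()
    if len(cancer) == 0 or len(benign) == 0:
        return cancer, benign
    merged = cancer[cancer["status"] == "cancer_case"][
        ["participant_id", "index_date"]
    ].merge(
        benign[benign["status"] == "benign_case"][["participant_id", "index_date"]],
        on="participant_id",
        suffixes=("_cancer", "_benign"),
    )
    if len(merged) == 0:
        return cancer, benign
    delta_days = (
        (merged["index_date_cancer"] - merged["index_date_benign"])
        .abs()
        .dt.total_seconds()
        / 86400.0
    )
    flagged = merged.loc[
        delta_days < window_months * DAYS_PER_MONTH, "participant_id"
    ]
    for table in (cancer, benign):
        hit = table["participant_id"].isin(flagged)
        table.loc[hit, "status"] = "excluded"
        table.loc[hit, "exclusion_reason"] = "diagnostic_uncertainty"
    logger.info(
        "dual-diagnosis window (%s months): %d participants excluded from both analyses",
        window_months,
        len(flagged),
    )
    return cancer, benign


def define_t2dm_status(participants: pd.DataFrame) -> pd.Series:
    """Type 2 diabetes flag from the baseline questionnaire.

    True iff the participant self-reports doctor-diagnosed diabetes AND was
    diagnosed at age >= 35 AND did not start insulin within the first year
    AND was diagnosed at least a year before enrollment — the standard
    screen against inadvertently counting type 1 diabetes. Missing subfields
    fail the criterion (conservative; counts are logged).
    """
    sr = participants["self_report_diabetes"].fillna(False).astype(bool)
    age_dx = pd.to_numeric(participants["age_at_diabetes_diagnosis"], errors="coerce")
    insulin = participants["insulin_within_first_year"]
    # nullable boolean: only an explicit False passes
    insulin_ok = insulin.notna() & (insulin == False)  # noqa: E712
    age_ok = age_dx >= 35
    recency_ok = (participants["age_at_recruitment"] - age_dx) >= 1
    status = sr & age_ok & insulin_ok & recency_ok
    n_missing = int((sr & (age_dx.isna() | insulin.isna())).sum())
    if n_missing:
        logger.info(
            "T2DM definition: %d self-reporters failed on missing subfields", n_missing
        )
    return pd.Series(
        np.asarray(status, dtype=bool), index=participants.index, name="t2dm"
    )


def select_controls(
    participants: pd.DataFrame,
    diagnoses: pd.DataFrame,
    outcome: str,
    case_table: pd.DataFrame,
) -> pd.DataFrame:
    """Complete the case/control/excluded partition for one outcome.

    Cancer controls require no C-prefixed (any malignancy) diagnosis; benign
    controls require no D34 record of any kind (a toxic nodule is still
    nodular disease, so its carrier is neither case nor control).
    """
    if outcome not in ("cancer", "benign"):
        raise ValueError("outcome must be 'cancer' or 'benign'")
    validate_diagnoses(diagnoses)
    codes = diagnoses["icd10_code"].astype(str)
    if outcome == "cancer":
        history_ids = set(diagnoses.loc[codes.str.startswith("C"), "participant_id"])
        history_reason = "cancer_history"
    else:
        history_ids = set(diagnoses.loc[codes.str.startswith("D34"), "participant_id"])
        history_reason = "nodular_disease_history"

    ids = participants.index
    out = pd.DataFrame(
        {
            "status": f"{outcome}_control",
            "exclusion_reason": "",
            "index_date": pd.NaT,
        },
        index=ids,
    )
    history_mask = ids.isin(history_ids)
    out.loc[history_mask, "status"] = "excluded"
    out.loc[history_mask, "exclusion_reason"] = history_reason

    if len(case_table):
        assigned = case_table.set_index("participant_id")
        shared = assigned.index.intersection(ids)
        cols = ["status", "exclusion_reason", "index_date"]
        out.loc[shared, cols] = assigned.loc[shared, cols]

    out = out.rename_axis("participant_id").reset_index()
    out["index_date"] = pd.to_datetime(out["index_date"])
    logger.info(
        "%s analysis: %d cases, %d controls, %d excluded",
        outcome,
        int((out["status"] == f"{outcome}_case").sum()),
        int((out["status"] == f"{outcome}_control").sum()),
        int((out["status"] == "excluded").sum()),
    )
    return out


def sensitivity_exclude_thyroid_dysfunction(
    assignment: pd.DataFrame,
    diagnoses: pd.DataFrame,
    code_prefixes: Sequence[str] = DEFAULT_DYSFUNCTION_CODES,
) -> pd.DataFrame:
    """Remove participants with thyroid-dysfunction codes from cases and controls.

    Supports the sensitivity analysis re-running one-sample MR after dropping
    anyone with hypo- or hyperthyroidism. An empty code list warns and
    returns the assignment unchanged.
    """
    if len(list(code_prefixes)) == 0:
        warnings.warn("empty dysfunction code list: sensitivity exclusion is a no-op")
        return assignment.copy()
    codes = diagnoses["icd10_code"].astype(str)
    flagged = set(
        diagnoses.loc[
            codes.str.startswith(tuple(code_prefixes)), "participant_id"
        ]
    )
    out = assignment.copy()
    hit = out["participant_id"].isin(flagged) & (out["status"] != "excluded")
    out.loc[hit, "status"] = "excluded"
    out.loc[hit, "exclusion_reason"] = "thyroid_dysfunction"
    logger.info(
        "sensitivity exclusion (%s): %d participants removed",
        ",".join(code_prefixes),
        int(hit.sum()),
    )
    return out


def build_cohort(
    participants: pd.DataFrame,
    diagnoses: pd.DataFrame,
    window_months: float = 12,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Run the full phenotyping chain; returns assignments per outcome + T2DM flag."""
    cancer_cases = define_thyroid_cancer_cases(diagnoses)
    benign_cases = define_benign_cases(diagnoses)
    cancer_cases, benign_cases = apply_dual_diagnosis_exclusion(
        cancer_cases, benign_cases, window_months
    )
    cancer = select_controls(participants, diagnoses, "cancer", cancer_cases)
    benign = select_controls(participants, diagnoses, "benign", benign_cases)
    return {
        "cancer": cancer,
        "benign": benign,
        "t2dm": define_t2dm_status(participants),
    }


def assignment_counts(assignment: pd.DataFrame) -> dict[str, int]:
    """Audit-trail counts (cases / controls / per-reason exclusions)."""
    counts: dict[str, int] = {}
    for status, group in assignment.groupby("status"):
        if status == "excluded":
            for reason, sub in group.groupby("exclusion_reason"):
                counts[f"excluded_{reason}"] = len(sub)
        else:
            counts[str(status)] = len(group)
    return counts
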