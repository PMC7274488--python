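"""Readers and writers for the pipeline's delimited-text interfaces.

Formats:

* variant weights — TSV with columns variant_id, effect_allele, other_allele,
  beta, eaf, trait;
* genotype dosages — TSV, header row of variant ids, row key participant_id,
  cells in [0, 2];
* cohort — participants CSV (one row per participant) plus a long-format
  diagnoses CSV (participant_id, icd10_code, diagnosis_date, histology_class,
  toxic_flag);
* summary statistics — TSV with variant_id, effect_allele, other_allele,
  beta_exp, se_exp, beta_out, se_out;
* cohort assignments — CSV with participant_id, status, exclusion_reason,
  index_date.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .types import VariantSpec


def write_variant_specs(specs: Sequence[VariantSpec], path: str | Path) -> None:
    pd.DataFrame(
        {
            "variant_id": [s.variant_id for s in specs],
            "effect_allele": [s.effect_allele for s in specs],
            "other_allele": [s.other_allele for s in specs],
            "beta": [s.beta for s in specs],
            "eaf": [s.eaf for s in specs],
            "trait": [s.trait for s in specs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_variant_specs(path: str | Path) -> list[VariantSpec]:
    df = pd.read_csv(path, sep="\t")
    return [
        VariantSpec(
            variant_id=str(r.variant_id),
            effect_allele=str(r.effect_allele),
            other_allele=str(r.other_allele),
            beta=float(r.beta),
            eaf=float(r.eaf),
            trait=str(r.trait),
        )
        for r in df.itertuples()
    ]


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="participant_id")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="participant_id")


def write_participants(participants: pd.DataFrame, path: str | Path) -> None:
    participants.to_csv(path, index_label="participant_id")


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, index_col="participant_id", parse_dates=["enrollment_date"]
    )
    if "insulin_within_first_year" in df.columns:
        df["insulin_within_first_year"] = df["insulin_within_first_year"].astype(
            "boolean"
        )
    return df


def write_diagnoses(diagnoses: pd.DataFrame, path: str | Path) -> None:
    diagnoses.to_csv(path, index=False)


def read_diagnoses(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["diagnosis_date"])


def write_summary_stats(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_assignment(assignment: pd.DataFrame, path: str | Path) -> None:
    assignment.to_csv(path, index=False)


def read_assignment(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["index_date"])
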