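"""Synthetic cohorts and summary statistics with the structure the analyses assume.

The real study population (a national biobank of ~380 000 unrelated
middle-aged adults with registry linkage) is access-restricted, so every
downstream stage is exercised on cohorts drawn here. The generator encodes
the canonical instrumental-variable diagram: independent biallelic variants
under Hardy–Weinberg equilibrium drive a continuous exposure; a single latent
standard-normal confounder ``U`` enters both the exposure and the outcome
linear predictors; the rare binary outcome follows a logistic model whose
intercept is calibrated to a target marginal prevalence. Registry-style
diagnosis records and questionnaire covariates are attached so that the
phenotyping rule engine can be run end to end.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; sub-draws are consumed in a fixed, documented
order (genotypes, confounder, exposure noise, outcome, covariates, records),
so equal seeds give byte-identical cohorts.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .types import CalibrationError, SimConfig, VariantSpec, validate_specs

# Default instrument-panel sizes per trait. BMI (73) and favourable adiposity
# (14) match the published instrument sets for those traits; the remaining
# panels are plausible sizes for GWAS of that era, fixed once as defaults.
TRAIT_PANEL_SIZES: dict[str, int] = {
    "BMI": 73,
    "WHR": 39,
    "adjWHR": 48,
    "T2DM": 38,
    "FA": 14,
    "HDL": 70,
    "LDL": 57,
    "TG": 40,
}

# Mean / SD used to express the simulated standardized exposure in natural
# units (the SDs echo the analysis population's: e.g. 4.8 kg/m^2 for BMI,
# 0.38 mmol/L for HDL).
TRAIT_UNITS: dict[str, tuple[float, float]] = {
    "BMI": (27.4, 4.8),
    "WHR": (0.87, 0.09),
    "HDL": (1.45, 0.38),
    "LDL": (3.56, 0.87),
    "TG": (1.75, 1.00),
}

_SMOKING_LEVELS = ("never", "former", "current", "missing")
_SMOKING_PROBS = (0.54, 0.35, 0.095, 0.015)

#: background (non-outcome) diagnosis rates used to populate realistic
#: registry noise: breast cancer, hypothyroidism, hyperthyroidism.
DEFAULT_BACKGROUND_CODES: dict[str, float] = {"C50": 0.02, "E03": 0.01, "E05": 0.003}


class SimulatedCohort(NamedTuple):
    """Genotypes plus the two-table realisation of the participant records."""

    genotypes: pd.DataFrame  # participants x variants dosage matrix
    participants: pd.DataFrame  # one row per participant
    diagnoses: pd.DataFrame  # long-format registry records
    truth: dict  # generator-level ground truth (intercept, exposure, U)


def default_variant_panel(
    trait: str = "BMI", n_variants: int | None = None, seed: int = 0
) -> list[VariantSpec]:
    """Build a default instrument panel for ``trait``.

    Effect-allele frequencies are drawn uniform(0.05, 0.95) and per-allele
    weights as |N(0, 0.03)| + 0.005 SD units, already oriented to the
    trait-increasing allele. The published instrument tables are not inputs
    here; only the panel sizes are anchored to the traits' known instrument
    counts.
    """
    if n_variants is None:
        n_variants = TRAIT_PANEL_SIZES.get(trait, 40)
    rng = np.random.default_rng(seed)
    ids = rng.choice(90_000_000, size=n_variants, replace=False) + 1_000_000
    bases = np.array(list("ACGT"))
    specs = []
    for j in range(n_variants):
        ea, oa = rng.choice(bases, size=2, replace=False)
        specs.append(
            VariantSpec(
                variant_id=f"rs{ids[j]}",
                effect_allele=str(ea),
                other_allele=str(oa),
                beta=float(abs(rng.normal(0.0, 0.03)) + 0.005),
                eaf=float(rng.uniform(0.05, 0.95)),
                trait=trait,
            )
        )
    return specs


def simulate_genotypes(
    specs: Sequence[VariantSpec], n: int, seed: int
) -> pd.DataFrame:
    """Draw an n x m dosage matrix, each column binomial(2, eaf) under HWE.

    Variants are independent (no linkage disequilibrium) and individuals are
    unrelated, mirroring the post-QC analysis set the estimators assume.
    """
    validate_specs(specs)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eaf = np.array([s.eaf for s in specs])
    dosages = rng.binomial(2, eaf, size=(n, len(specs))).astype(np.int8)
    index = pd.Index([f"P{i:07d}" for i in range(n)], name="participant_id")
    return pd.DataFrame(dosages, index=index, columns=[s.variant_id for s in specs])


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Root-find the logistic intercept giving the target marginal prevalence."""

    def gap(b0: float) -> float:
        return float(expit(b0 + eta).mean() - prevalence)

    lo, hi = -40.0, 15.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"cannot calibrate intercept for prevalence {prevalence}"
        )
    return float(brentq(gap, lo, hi, xtol=1e-12))


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate genotypes, participant records, and registry diagnoses.

    Exposure construction: let ``z`` be the standardized weighted allele
    score. Then ``x* = sqrt(r2)*z + c_x*U + sigma*eps`` with
    ``sigma^2 = 1 - r2 - c_x^2`` (so the score explains exactly ``r2`` of the
    exposure variance in the population), and the exposure is ``x*``
    standardized to sample mean 0, SD 1. The outcome linear predictor is
    ``b0 + causal_effect*x + c_y*U`` with ``b0`` calibrated by root-finding.

    Raises
    ------
    CalibrationError
        if no participant is a case at the requested ``n`` (advice: increase
        ``n_participants`` or the baseline prevalence).
    """
    cfg = config
    n = cfg.n_participants
    rng = np.random.default_rng(cfg.seed)
    geno_seed = int(rng.integers(2**31 - 1))
    genotypes = simulate_genotypes(cfg.variant_specs, n, geno_seed)

    betas = np.array([s.beta for s in cfg.variant_specs])
    raw_score = genotypes.to_numpy() @ betas
    sd = raw_score.std()
    if sd == 0:
        raise CalibrationError("allele score is constant; increase n or panel size")
    z = (raw_score - raw_score.mean()) / sd

    c_x = cfg.confounder_effect_on_exposure
    noise_var = 1.0 - cfg.instrument_r2 - c_x**2
    if noise_var <= 0:
        raise ValueError(
            "confounder_effect_on_exposure^2 must be < 1 - instrument_r2 "
            "for a unit-variance exposure"
        )
    confounder = rng.standard_normal(n)
    x_star = (
        math.sqrt(cfg.instrument_r2) * z
        + c_x * confounder
        + math.sqrt(noise_var) * rng.standard_normal(n)
    )
    exposure = (x_star - x_star.mean()) / x_star.std()

    eta = cfg.causal_effect * exposure + cfg.confounder_effect_on_outcome * confounder
    intercept = _calibrate_intercept(eta, cfg.outcome_baseline_prevalence)
    case = rng.random(n) < expit(intercept + eta)
    if not case.any():
        raise CalibrationError(
            "no cases realized at the requested sample size; "
            "increase n_participants (or outcome_baseline_prevalence)"
        )

    participants = _make_participants(rng, genotypes.index, exposure, case, cfg)
    diagnoses = _make_diagnoses(rng, participants, case, cfg)
    truth = {
        "intercept": intercept,
        "exposure": exposure,
        "confounder": confounder,
        "allele_score_std": z,
    }
    return SimulatedCohort(genotypes, participants, diagnoses, truth)


def _make_participants(
    rng: np.random.Generator,
    index: pd.Index,
    exposure: np.ndarray,
    case: np.ndarray,
    cfg: SimConfig,
) -> pd.DataFrame:
    n = len(index)
    df = pd.DataFrame(index=index)
    df["sex"] = np.where(rng.random(n) < 0.54, "F", "M")
    df["age_at_recruitment"] = rng.integers(40, 70, size=n)
    enroll_offset = rng.integers(0, 1460, size=n)  # recruitment window ~4 years
    df["enrollment_date"] = np.datetime64("2006-04-01") + enroll_offset.astype(
        "timedelta64[D]"
    )
    df["smoking"] = rng.choice(_SMOKING_LEVELS, size=n, p=_SMOKING_PROBS)
    df["alcohol_units_week"] = np.round(rng.gamma(1.5, 6.0, size=n), 1)
    df["townsend"] = np.round(rng.normal(-1.4, 3.0, size=n), 3)

    # Anthropometry / biomarkers. The trait under study is mapped from the
    # standardized exposure into natural units; the rest are independent.
    for trait, (mu, s) in TRAIT_UNITS.items():
        col = trait.lower()
        if col in df.columns:
            continue
        if trait == cfg.variant_specs[0].trait:
            df[col] = mu + s * exposure
        else:
            df[col] = mu + s * rng.standard_normal(n)
    if cfg.variant_specs[0].trait == "adjWHR":
        df["whr"] = TRAIT_UNITS["WHR"][0] + TRAIT_UNITS["WHR"][1] * exposure
    df["glucose"] = 5.1 + 1.2 * rng.standard_normal(n)

    # Questionnaire diabetes fields (independent of the simulated outcome).
    sr = rng.random(n) < 0.045
    age_dx = np.where(sr, rng.integers(25, 69, size=n), np.nan)
    age_dx = np.minimum(age_dx, df["age_at_recruitment"].to_numpy())
    df["self_report_diabetes"] = sr
    df["age_at_diabetes_diagnosis"] = age_dx
    insulin = pd.array(rng.random(n) < 0.12, dtype="boolean")
    insulin[~sr] = pd.NA
    df["insulin_within_first_year"] = insulin

    centre = rng.integers(1, 11, size=n)
    df["assessment_centre"] = np.array([f"c{c:02d}" for c in range(1, 11)])[centre - 1]
    df["genotyping_platform"] = np.where(rng.random(n) < 0.9, "axiom", "bileve")
    for k in range(1, 6):
        df[f"pc{k}"] = rng.standard_normal(n)
    df["exposure"] = exposure
    df["true_case"] = case
    return df


def _make_diagnoses(
    rng: np.random.Generator,
    participants: pd.DataFrame,
    case: np.ndarray,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Registry rows: outcome diagnoses for cases plus background noise codes."""
    rows: list[pd.DataFrame] = []
    ids = participants.index.to_numpy()
    enroll = participants["enrollment_date"].to_numpy()

    case_ids = ids[case]
    n_cases = len(case_ids)
    if n_cases:
        # registry linkage is longitudinal: diagnoses fall within roughly
        # five years before to eight years after enrollment
        offsets = rng.integers(-1826, 2922, size=n_cases).astype("timedelta64[D]")
        if cfg.outcome == "cancer":
            code = "C73"
            histology = rng.choice(
                ["papillary", "follicular"], size=n_cases, p=[0.8, 0.2]
            )
            toxic = np.zeros(n_cases, dtype=bool)
        else:
            code = "D34"
            histology = np.full(n_cases, "not_applicable")
            toxic = np.zeros(n_cases, dtype=bool)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": case_ids,
                    "icd10_code": code,
                    "diagnosis_date": enroll[case] + offsets,
                    "histology_class": histology,
                    "toxic_flag": toxic,
                }
            )
        )

    for code, rate in DEFAULT_BACKGROUND_CODES.items():
        hit = rng.random(len(ids)) < rate
        if not hit.any():
            continue
        offsets = rng.integers(-1826, 2922, size=int(hit.sum())).astype(
            "timedelta64[D]"
        )
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": ids[hit],
                    "icd10_code": code,
                    "diagnosis_date": enroll[hit] + offsets,
                    "histology_class": "not_applicable",
                    "toxic_flag": False,
                }
            )
        )

    if not rows:
        return pd.DataFrame(
            columns=[
                "participant_id",
                "icd10_code",
                "diagnosis_date",
                "histology_class",
                "toxic_flag",
            ]
        )
    out = pd.concat(rows, ignore_index=True)
    out["diagnosis_date"] = pd.to_datetime(out["diagnosis_date"])
    return out.sort_values(["participant_id", "diagnosis_date"]).reset_index(drop=True)


def simulate_summary_stats(
    specs: Sequence[VariantSpec],
    causal_effect: float,
    n_exp: int,
    n_out: int,
    pleiotropy_mode: str = "none",
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw harmonizable two-sample GWAS summary statistics.

    Per variant j with true per-allele effect ``b_j`` and frequency ``p_j``:

    * ``se_exp = 1 / sqrt(2 p_j (1-p_j) n_exp)`` (the SE of a per-allele
      regression slope for a unit-variance trait), ``beta_exp ~ N(b_j, se_exp)``;
    * ``beta_out ~ N(causal_effect * b_j + alpha_j, se_out)`` with ``se_out``
      analogous at ``n_out``;
    * ``alpha_j`` is 0 (no pleiotropy), N(0, pleiotropy_sd) (balanced) or
      N(pleiotropy_mean, pleiotropy_sd) (directional) — the horizontal
      pathway that IVW assumes absent and Egger's intercept absorbs.
    """
    validate_specs(specs)
    if n_exp < 2 or n_out < 2:
        raise ValueError("sample sizes must be >= 2")
    if pleiotropy_mode not in ("none", "balanced", "directional"):
        raise ValueError("pleiotropy_mode must be none/balanced/directional")
    if pleiotropy_sd < 0:
        raise ValueError("pleiotropy_sd must be >= 0")
    rng = np.random.default_rng(seed)
    b = np.array([s.beta for s in specs])
    p = np.array([s.eaf for s in specs])
    se_exp = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * n_exp)
    se_out = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * n_out)
    if pleiotropy_mode == "none":
        alpha = np.zeros(len(specs))
    else:
        mean = pleiotropy_mean if pleiotropy_mode == "directional" else 0.0
        alpha = rng.normal(mean, pleiotropy_sd, size=len(specs))
    beta_exp = rng.normal(b, se_exp)
    beta_out = rng.normal(causal_effect * b + alpha, se_out)
    return pd.DataFrame(
        {
            "variant_id": [s.variant_id for s in specs],
            "effect_allele": [s.effect_allele for s in specs],
            "other_allele": [s.other_allele for s in specs],
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "beta_out": beta_out,
            "se_out": se_out,
        }
    )
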