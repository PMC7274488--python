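"""Shared domain types and exceptions."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

_BASES = {"A", "C", "G", "T"}

TRAITS = ("BMI", "WHR", "adjWHR", "T2DM", "FA", "HDL", "LDL", "TG")

PLEIOTROPY_MODES = ("none", "balanced", "directional")


class CalibrationError(RuntimeError):
    """Raised when the outcome-prevalence calibration cannot be satisfied."""


class SeparationError(RuntimeError):
    """Raised when a logistic fit fails to converge (e.g. perfect separation)."""


class WeakInstrumentWarning(UserWarning):
    """Emitted when a first-stage F statistic falls below the conventional 10."""


@dataclass(frozen=True)
class VariantSpec:
    """One instrument variant: alleles, per-allele weight, effect-allele frequency.

    ``beta`` is the per-allele effect on the trait in SD units for continuous
    traits, or log-odds for binary traits, as reported by the source GWAS.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    eaf: float
    trait: str = "BMI"

    def __post_init__(self) -> None:
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(
                f"{self.variant_id}: effect-allele frequency must lie in (0, 1), got {self.eaf}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in _BASES:
                raise ValueError(f"{self.variant_id}: allele {allele!r} is not a single base")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: non-finite weight")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


def validate_specs(specs: Sequence[VariantSpec]) -> None:
    """Check a weight set is nonempty with unique variant ids."""
    if len(specs) == 0:
        raise ValueError("variant spec list is empty")
    ids = [s.variant_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({v for v in ids if ids.count(v) > 1})
        raise ValueError(f"duplicate variant ids in weight set: {dupes}")


@dataclass
class SimConfig:
    """Configuration of one simulated cohort.

    The exposure is built as a weighted allele score plus a shared latent
    confounder ``U`` plus noise, then standardized; the binary outcome is
    drawn from a logistic model whose intercept is calibrated by root-finding
    so that the marginal prevalence matches ``outcome_baseline_prevalence``.

    ``instrument_r2`` is the fraction of exposure variance explained by the
    allele score (default 1.5%, a typical polygenic-score yield for an
    anthropometric trait).
    """

    n_participants: int
    variant_specs: Sequence[VariantSpec]
    causal_effect: float = 0.0
    confounder_effect_on_exposure: float = 0.5
    confounder_effect_on_outcome: float = 0.5
    outcome_baseline_prevalence: float = 0.005
    outcome: str = "benign"  # "benign" -> D34 records, "cancer" -> C73 records
    instrument_r2: float = 0.015
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (0.0 < self.outcome_baseline_prevalence < 1.0):
            raise ValueError("outcome_baseline_prevalence must lie in (0, 1)")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if self.outcome not in ("benign", "cancer"):
            raise ValueError("outcome must be 'benign' or 'cancer'")
        if not (0.0 < self.instrument_r2 < 1.0):
            raise ValueError("instrument_r2 must lie in (0, 1)")
        validate_specs(self.variant_specs)


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty.

    ``beta`` is the causal log-odds ratio per SD of exposure (or the log-OR of
    a quartile contrast); the confidence bounds are reported on the OR scale,
    matching the convention of epidemiological result tables.
    """

    method: str
    beta: float
    se: float
    ci95_low: float
    ci95_high: float
    p: float
    egger_intercept: float | None = None
    intercept_p: float | None = None
    n_variants: int | None = None
    n_participants: int | None = None
    f_stat: float | None = None
    q_stat: float | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"standard error must be positive, got {self.se}")
        oratio = math.exp(self.beta)
        if not (self.ci95_low - 1e-12 <= oratio <= self.ci95_high + 1e-12):
            raise ValueError(
                f"odds ratio {oratio:.6g} outside its CI [{self.ci95_low:.6g}, {self.ci95_high:.6g}]"
            )

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


@dataclass
class AssocResult:
    """One covariate-adjusted logistic association (observational analysis)."""

    trait: str
    outcome: str
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float
    n_cases: int
    n_controls: int
    covariate_set: tuple[str, ...]
    stratum: str = "all"
    sd_used: float | None = None  # SD of the predictor when per-SD scaled

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.ci95_low - 1e-12 <= self.odds_ratio <= self.ci95_high + 1e-12):
            raise ValueError("odds ratio outside its confidence interval")
        if self.stratum not in ("all", "female", "male"):
            raise ValueError("stratum must be all/female/male")
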