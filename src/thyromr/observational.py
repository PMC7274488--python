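"""Covariate-adjusted logistic associations between measured traits and outcomes.

Continuous predictors are reported as odds ratios per 1 SD of the analysis
population (the SD used is carried alongside each result); skewed
questionnaire measures such as weekly alcohol units are rank-based
inverse-normal transformed first. Confidence intervals are Wald intervals on
the exponentiated coefficient, matching the OR (95% CI) reporting style of
case-control tables.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._design import build_design
from .types import AssocResult, SeparationError

logger = logging.getLogger(__name__)

#: default adjustment set for trait-outcome models: age, sex, smoking status,
#: alcohol consumption, Townsend deprivation index, BMI, and T2DM status
DEFAULT_COVARIATES = (
    "age_at_recruitment",
    "sex",
    "smoking",
    "alcohol_units_week",
    "townsend",
    "bmi",
    "t2dm",
)

#: minimal adjustment used for demographic case/control comparisons
AGE_SEX_COVARIATES = ("age_at_recruitment", "sex")


def standardize_per_sd(values: pd.Series | np.ndarray) -> tuple[np.ndarray, float]:
    """Center and scale by the analysis population's SD; returns (z, SD)."""
    arr = pd.Series(values).astype(float)
    nonmiss = arr.dropna()
    if len(nonmiss) < 2:
        raise ValueError("need at least 2 non-missing values")
    sd = float(nonmiss.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance: cannot standardize a constant column")
    return ((arr - nonmiss.mean()) / sd).to_numpy(), sd


def inverse_normal_transform(values: pd.Series | np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((rank - 0.5) / n).

    Ties share their average rank; an all-tied input maps to all zeros.
    Missing values stay missing.
    """
    arr = pd.Series(values).astype(float).to_numpy()
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n == 0:
        return out
    ranks = stats.rankdata(arr[mask], method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def _fit_logit(y: np.ndarray, X: pd.DataFrame, cov_type: str = "nonrobust"):
    """Fit a logistic model, translating failure modes into SeparationError."""
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(
                disp=0, maxiter=200, method="newton", cov_type=cov_type
            )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise SeparationError(f"logistic fit failed: {e}") from e
    if not fit.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (possible separation)")
    if not np.all(np.isfinite(fit.bse)):
        raise SeparationError("non-finite standard errors (possible separation)")
    return fit


def logistic_association(
    data: pd.DataFrame,
    outcome: str,
    trait: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    stratum: str = "all",
    per_sd: bool = True,
    min_cases: int = 10,
) -> AssocResult:
    """Maximum-likelihood logistic association of ``trait`` with ``outcome``.

    ``outcome`` must be a binary column; ``trait`` is standardized per SD
    unless ``per_sd=False`` (e.g. for binary or categorical exposures). The
    trait itself is dropped from the covariate list when present, complete
    cases only are analysed, and sex-stratified fits drop the sex covariate.
    Refuses to report when fewer than ``min_cases`` cases remain.
    """
    if stratum not in ("all", "female", "male"):
        raise ValueError("stratum must be all/female/male")
    df = data
    if stratum != "all":
        df = df[df["sex"] == ("F" if stratum == "female" else "M")]
    covs = [c for c in covariates if c != trait and c in df.columns]
    if stratum != "all" and "sex" in covs:
        covs.remove("sex")

    cols = [outcome, trait] + covs
    complete = df[cols].dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info(
            "%s ~ %s: %d records dropped for missingness", outcome, trait, n_dropped
        )
    y = complete[outcome].astype(int).to_numpy()
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    if n_cases < min_cases:
        raise ValueError(
            f"only {n_cases} cases after exclusions (< {min_cases}); refusing to fit"
        )

    sd_used = None
    if per_sd:
        x, sd_used = standardize_per_sd(complete[trait])
    else:
        x = complete[trait].astype(float).to_numpy()
    X = pd.concat(
        [
            pd.DataFrame({trait: x}, index=complete.index),
            build_design(complete[covs]),
        ],
        axis=1,
    )
    X = sm.add_constant(X)
    fit = _fit_logit(y, X)

    beta = float(fit.params[trait])
    se = float(fit.bse[trait])
    zcrit = stats.norm.ppf(0.975)
    return AssocResult(
        trait=trait,
        outcome=outcome,
        odds_ratio=float(np.exp(beta)),
        ci95_low=float(np.exp(beta - zcrit * se)),
        ci95_high=float(np.exp(beta + zcrit * se)),
        p_value=float(fit.pvalues[trait]),
        n_cases=n_cases,
        n_controls=n_controls,
        covariate_set=tuple(covs),
        stratum=stratum,
        sd_used=sd_used,
    )
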