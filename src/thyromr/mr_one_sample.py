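"""One-sample Mendelian randomization: two-stage estimation and GRS quartiles.

Stage 1 regresses the continuous exposure on the genetic risk score plus
covariates (age, sex, assessment centre, principal components, genotyping
platform); stage 2 regresses disease status on the stage-1 fitted values plus
the same covariates with a logistic link. The stage-2 coefficient on the
fitted values is the causal log-OR per SD of exposure. Because alleles are
fixed at conception, the fitted values are purged of confounding, so this
estimate is immune to the biases of the observational fit on the same data.

Standard errors are heteroskedasticity-consistent (HC1 sandwich) to absorb
uncertainty carried over from the first stage; a first-stage F below 10
attaches a weak-instrument warning to the result rather than failing.

For a binary exposure such as T2DM the ratio estimate is hard to interpret,
so the module instead offers the quartile contrast: participants are binned
by genetic-liability quartile and each upper quartile is compared with the
lowest by logistic regression, alongside crude cross-product odds ratios from
the 2x2 counts.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._design import build_design
from .observational import _fit_logit
from .types import MREstimate, WeakInstrumentWarning

#: covariates for both MR stages
DEFAULT_MR_COVARIATES = (
    "age_at_recruitment",
    "sex",
    "assessment_centre",
    "genotyping_platform",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
    "pc5",
)

_Z95 = stats.norm.ppf(0.975)


def two_stage_mr(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    instrument: str,
    covariates: Sequence[str] = DEFAULT_MR_COVARIATES,
    control_function: bool = False,
    family: str = "logit",
) -> MREstimate:
    """Two-stage MR of ``outcome`` on ``exposure`` instrumented by ``instrument``.

    Predictor substitution by default: the stage-1 fitted values replace the
    exposure in stage 2. With ``control_function=True`` the stage-1 residuals
    are added as an extra regressor instead (the control-function variant).
    ``family`` may be "logit" (binary outcome, default) or "linear".
    """
    covs = [c for c in covariates if c in data.columns]
    cols = [outcome, exposure, instrument] + covs
    df = data[cols].dropna().reset_index(drop=True)
    n = len(df)

    cov_design = build_design(df[covs])
    X1 = sm.add_constant(
        pd.concat([df[[instrument]].astype(float), cov_design], axis=1)
    )
    stage1 = sm.OLS(df[exposure].astype(float), X1).fit()
    f_stat = float(stage1.tvalues[instrument] ** 2)
    notes: list[str] = []
    if f_stat < 10:
        warnings.warn(
            f"first-stage F = {f_stat:.2f} < 10: weak instrument",
            WeakInstrumentWarning,
        )
        notes.append(f"weak instrument (F = {f_stat:.2f})")

    if control_function:
        x2 = pd.DataFrame(
            {exposure: df[exposure].astype(float), "stage1_resid": stage1.resid}
        )
    else:
        x2 = pd.DataFrame({exposure: stage1.fittedvalues})
    X2 = sm.add_constant(pd.concat([x2, cov_design], axis=1))

    if family == "logit":
        y = df[outcome].astype(int).to_numpy()
        fit = _fit_logit(y, X2, cov_type="HC1")
        names = list(X2.columns)
        idx = names.index(exposure)
        beta = float(np.asarray(fit.params)[idx])
        se = float(np.asarray(fit.bse)[idx])
        p = float(np.asarray(fit.pvalues)[idx])
    elif family == "linear":
        fit = sm.OLS(df[outcome].astype(float), X2).fit(cov_type="HC1")
        beta = float(fit.params[exposure])
        se = float(fit.bse[exposure])
        p = float(fit.pvalues[exposure])
    else:
        raise ValueError("family must be 'logit' or 'linear'")

    return MREstimate(
        method="two_stage",
        beta=beta,
        se=se,
        ci95_low=float(np.exp(beta - _Z95 * se)),
        ci95_high=float(np.exp(beta + _Z95 * se)),
        p=p,
        n_participants=n,
        f_stat=f_stat,
        notes=tuple(notes),
    )


def crude_odds_ratio(
    cases: int, controls: int, cases_ref: int, controls_ref: int
) -> tuple[float, float, float]:
    """Cross-product OR of a quartile vs the reference, with a Woolf 95% CI."""
    if min(cases, controls, cases_ref, controls_ref) <= 0:
        raise ValueError("all four cell counts must be positive")
    oratio = (cases * controls_ref) / (controls * cases_ref)
    se = np.sqrt(1 / cases + 1 / controls + 1 / cases_ref + 1 / controls_ref)
    return (
        float(oratio),
        float(np.exp(np.log(oratio) - _Z95 * se)),
        float(np.exp(np.log(oratio) + _Z95 * se)),
    )


def quartile_counts(
    data: pd.DataFrame, outcome: str, quartile_col: str = "quartile"
) -> pd.DataFrame:
    """Case/control counts per genetic-liability quartile."""
    y = data[outcome].astype(bool)
    tab = (
        data.assign(_case=y)
        .groupby(quartile_col)["_case"]
        .agg(cases="sum", total="count")
        .reset_index()
        .rename(columns={quartile_col: "quartile"})
    )
    tab["cases"] = tab["cases"].astype(int)
    tab["controls"] = (tab["total"] - tab["cases"]).astype(int)
    return tab[["quartile", "cases", "controls"]]


def crude_quartile_ors(counts: pd.DataFrame) -> pd.DataFrame:
    """Crude ORs vs quartile 1 from a (quartile, cases, controls) count table."""
    counts = counts.sort_values("quartile").reset_index(drop=True)
    ref = counts.iloc[0]
    rows = []
    for _, r in counts.iterrows():
        if r["quartile"] == ref["quartile"]:
            rows.append((int(r["quartile"]), 1.0, np.nan, np.nan))
            continue
        oratio, lo, hi = crude_odds_ratio(
            int(r["cases"]), int(r["controls"]), int(ref["cases"]), int(ref["controls"])
        )
        rows.append((int(r["quartile"]), oratio, lo, hi))
    return pd.DataFrame(rows, columns=["quartile", "odds_ratio", "ci95_low", "ci95_high"])


def quartile_association(
    data: pd.DataFrame,
    outcome: str,
    quartile_col: str = "quartile",
    covariates: Sequence[str] = DEFAULT_MR_COVARIATES,
) -> list[MREstimate]:
    """Adjusted ORs for quartiles 2-4 vs quartile 1 of genetic liability.

    One logistic model with quartile indicators (quartile 1 reference) plus
    covariates; returns one estimate per contrast, each also carrying the
    participant count of the two quartiles involved.
    """
    covs = [c for c in covariates if c in data.columns]
    df = data[[outcome, quartile_col] + covs].dropna().reset_index(drop=True)
    quartiles = sorted(df[quartile_col].unique())
    if len(quartiles) < 2:
        raise ValueError("need at least two non-empty quartiles")
    counts = df.groupby(quartile_col)[outcome].count()
    if (counts == 0).any():
        raise ValueError("empty quartile in the analysis population")

    dummies = pd.get_dummies(
        df[quartile_col].astype(int), prefix="q", drop_first=True, dtype=float
    )
    X = sm.add_constant(pd.concat([dummies, build_design(df[covs])], axis=1))
    y = df[outcome].astype(int).to_numpy()
    fit = _fit_logit(y, X)

    results = []
    names = list(X.columns)
    for q in quartiles[1:]:
        col = f"q_{q}"
        idx = names.index(col)
        beta = float(np.asarray(fit.params)[idx])
        se = float(np.asarray(fit.bse)[idx])
        results.append(
            MREstimate(
                method="quartile",
                beta=beta,
                se=se,
                ci95_low=float(np.exp(beta - _Z95 * se)),
                ci95_high=float(np.exp(beta + _Z95 * se)),
                p=float(np.asarray(fit.pvalues)[idx]),
                n_participants=int(counts.loc[q] + counts.loc[quartiles[0]]),
                notes=(f"quartile {q} vs {quartiles[0]}",),
            )
        )
    return results
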