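"""Two-sample summary-statistic Mendelian randomization estimators.

Given per-variant harmonized exposure and outcome associations (beta, SE)
from non-overlapping GWAS, this module provides:

* the single-instrument Wald ratio ``beta_out / beta_exp`` with first-order
  (or optional second-order) delta-method SE;
* fixed-effect inverse-variance weighted (IVW) pooling — a weighted
  regression of outcome betas on exposure betas through the origin, exact
  closed form ``sum(w b_x b_y) / sum(w b_x^2)`` with ``w = 1/se_out^2`` and
  SE ``1/sqrt(sum(w b_x^2))`` — plus Cochran's Q heterogeneity diagnostic
  and an optional multiplicative random-effects SE;
* MR-Egger: the same weighted regression with a free intercept; the slope is
  the causal estimate under the InSIDE assumption and the intercept (with
  its p-value) estimates average directional pleiotropy;
* the weighted median of the per-variant Wald ratios (consistent while valid
  instruments carry >50% of the weight) and its penalized variant, which
  shrinks the weight of variants contributing outlying heterogeneity; both
  use a parametric bootstrap for the SE.

IVW assumes every instrument is valid; Egger and the median estimators relax
that assumption in complementary ways, which is why result tables report all
four side by side.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .types import MREstimate

logger = logging.getLogger(__name__)

_Z95 = stats.norm.ppf(0.975)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

REQUIRED_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "beta_out",
    "se_out",
)


def _validate(rows: pd.DataFrame, min_rows: int = 1) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(rows.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    if len(rows) < min_rows:
        raise ValueError(f"need at least {min_rows} instruments, got {len(rows)}")
    if (rows["se_exp"] <= 0).any() or (rows["se_out"] <= 0).any():
        raise ValueError("standard errors must be strictly positive")
    return rows


def merge_exposure_outcome(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    allow_strand_flip: bool = False,
) -> pd.DataFrame:
    """Join exposure and outcome statistics on variant id and shared alleles.

    Outcome rows whose alleles are swapped relative to the exposure have
    their beta sign-flipped; with ``allow_strand_flip`` the outcome alleles
    may also be complemented first. Variants whose alleles cannot be
    reconciled raise an error listing them.
    """
    merged = exposure.merge(
        outcome, on="variant_id", suffixes=("", "_o"), how="inner"
    )
    beta_out = np.empty(len(merged))
    se_out = merged["se_out"].to_numpy(dtype=float)
    bad: list[str] = []
    for i, row in enumerate(merged.itertuples()):
        ea, oa = row.effect_allele, row.other_allele
        ea_o, oa_o = row.effect_allele_o, row.other_allele_o
        if allow_strand_flip and {ea_o, oa_o} != {ea, oa}:
            ea_o, oa_o = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
        if (ea_o, oa_o) == (ea, oa):
            beta_out[i] = row.beta_out
        elif (ea_o, oa_o) == (oa, ea):
            beta_out[i] = -row.beta_out
        else:
            bad.append(row.variant_id)
            beta_out[i] = np.nan
    if bad:
        raise ValueError(f"allele mismatch between exposure and outcome for: {bad}")
    return pd.DataFrame(
        {
            "variant_id": merged["variant_id"],
            "effect_allele": merged["effect_allele"],
            "other_allele": merged["other_allele"],
            "beta_exp": merged["beta_exp"].astype(float),
            "se_exp": merged["se_exp"].astype(float),
            "beta_out": beta_out,
            "se_out": se_out,
        }
    )


def harmonize(rows: pd.DataFrame, palindromic: str = "keep") -> pd.DataFrame:
    """Orient every row to the exposure-increasing allele.

    Rows with negative exposure beta have both betas sign-flipped and their
    alleles swapped (the Wald ratio is invariant). Strand-ambiguous
    palindromic variants (A/T, C/G) are kept or dropped per policy.
    """
    if palindromic not in ("keep", "drop"):
        raise ValueError("palindromic policy must be 'keep' or 'drop'")
    out = _validate(rows).copy().reset_index(drop=True)
    if palindromic == "drop":
        pal = out.apply(
            lambda r: {r["effect_allele"], r["other_allele"]}
            in ({"A", "T"}, {"C", "G"}),
            axis=1,
        )
        if pal.any():
            logger.info(
                "dropping %d palindromic variants: %s",
                int(pal.sum()),
                ", ".join(out.loc[pal, "variant_id"]),
            )
        out = out[~pal].reset_index(drop=True)
    flip = out["beta_exp"] < 0
    out.loc[flip, ["beta_exp", "beta_out"]] *= -1
    ea = out.loc[flip, "effect_allele"].copy()
    out.loc[flip, "effect_allele"] = out.loc[flip, "other_allele"]
    out.loc[flip, "other_allele"] = ea
    out["harmonized"] = True
    return out


def wald_ratio(
    beta_exp: float,
    beta_out: float,
    se_exp: float,
    se_out: float,
    second_order: bool = False,
) -> tuple[float, float]:
    """Single-instrument causal estimate ``beta_out / beta_exp`` and its SE.

    First-order delta SE is ``se_out / |beta_exp|``; the second-order version
    adds the exposure-uncertainty term and reduces to it as ``se_exp -> 0``.
    """
    if beta_exp == 0:
        raise ZeroDivisionError("beta_exp is zero: Wald ratio undefined")
    ratio = beta_out / beta_exp
    if second_order:
        se = np.sqrt(
            se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4
        )
    else:
        se = se_out / abs(beta_exp)
    return float(ratio), float(se)


def _estimate(method: str, beta: float, se: float, p: float, **kw) -> MREstimate:
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci95_low=float(np.exp(beta - _Z95 * se)),
        ci95_high=float(np.exp(beta + _Z95 * se)),
        p=p,
        **kw,
    )


def ivw(rows: pd.DataFrame, random_effects: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance weighted estimate.

    With one instrument this reduces exactly to the Wald ratio. Cochran's Q
    about the pooled slope is attached; ``random_effects=True`` inflates the
    SE by ``max(1, sqrt(Q / (k - 1)))`` (multiplicative random effects).
    """
    rows = _validate(rows, min_rows=1)
    bx = rows["beta_exp"].to_numpy(dtype=float)
    by = rows["beta_out"].to_numpy(dtype=float)
    w = 1.0 / rows["se_out"].to_numpy(dtype=float) ** 2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise ValueError("all exposure betas are zero")
    beta = float(np.sum(w * bx * by) / denom)
    se = float(1.0 / np.sqrt(denom))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    k = len(rows)
    if random_effects and k > 1:
        se *= max(1.0, np.sqrt(q / (k - 1)))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return _estimate("ivw", beta, se, p, n_variants=k, q_stat=q)


def egger(rows: pd.DataFrame) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Needs >= 3 instruments (slope + intercept + residual df). The SE uses the
    multiplicative-error convention: the fixed-effect SE from the weighted
    design inflated by ``max(1, sqrt(RSS_w / (k - 2)))``, with t(k-2)
    p-values. The intercept p-value is the directional-pleiotropy test.
    """
    rows = _validate(rows, min_rows=3)
    bx = rows["beta_exp"].to_numpy(dtype=float)
    by = rows["beta_out"].to_numpy(dtype=float)
    w = 1.0 / rows["se_out"].to_numpy(dtype=float) ** 2
    k = len(rows)
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    try:
        cov_fixed = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as e:
        raise ValueError("degenerate design (constant exposure betas?)") from e
    coef = cov_fixed @ (X.T @ (w * by))
    resid = by - X @ coef
    sigma = float(np.sqrt(np.sum(w * resid**2) / (k - 2)))
    scale = max(1.0, sigma)
    se = np.sqrt(np.diag(cov_fixed)) * scale
    tdist = stats.t(df=k - 2)
    p_slope = float(2 * tdist.sf(abs(coef[1]) / se[1]))
    p_int = float(2 * tdist.sf(abs(coef[0]) / se[0]))
    tcrit = float(tdist.ppf(0.975))
    return MREstimate(
        method="egger",
        beta=float(coef[1]),
        se=float(se[1]),
        ci95_low=float(np.exp(coef[1] - tcrit * se[1])),
        ci95_high=float(np.exp(coef[1] + tcrit * se[1])),
        p=p_slope,
        egger_intercept=float(coef[0]),
        intercept_p=p_int,
        n_variants=k,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50% point of the weighted empirical distribution."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if s[0] >= 0.5:
        return float(v[0])
    if s[-1] <= 0.5:
        return float(v[-1])
    i = int(np.searchsorted(s, 0.5, side="right")) - 1
    return float(v[i] + (v[i + 1] - v[i]) * (0.5 - s[i]) / (s[i + 1] - s[i]))


def _ratio_inputs(rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bx = rows["beta_exp"].to_numpy(dtype=float)
    by = rows["beta_out"].to_numpy(dtype=float)
    if (bx == 0).any():
        raise ZeroDivisionError("zero exposure beta: ratio undefined")
    ratios = by / bx
    se_ratio = rows["se_out"].to_numpy(dtype=float) / np.abs(bx)
    return ratios, 1.0 / se_ratio**2


def _bootstrap_se(
    rows: pd.DataFrame,
    point_fn: Callable[[pd.DataFrame], float],
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: resample betas from their sampling distributions."""
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    base = rows.copy()
    bx = rows["beta_exp"].to_numpy(dtype=float)
    by = rows["beta_out"].to_numpy(dtype=float)
    sx = rows["se_exp"].to_numpy(dtype=float)
    sy = rows["se_out"].to_numpy(dtype=float)
    for b in range(n_boot):
        base["beta_exp"] = rng.normal(bx, sx)
        base["beta_out"] = rng.normal(by, sy)
        boots[b] = point_fn(base)
    return float(np.std(boots, ddof=1))


def weighted_median(
    rows: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator over per-variant Wald ratios.

    Weights are inverse-variance weights of the ratios (first-order SEs); the
    estimate is the linear interpolation where the standardized cumulative
    weight crosses 0.5. SE by parametric bootstrap with ``n_boot`` resamples.
    """
    rows = _validate(rows, min_rows=3)

    def point(df: pd.DataFrame) -> float:
        return _weighted_median(*_ratio_inputs(df))

    beta = point(rows)
    se = _bootstrap_se(rows, point, n_boot, seed)
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return _estimate("weighted_median", beta, se, p, n_variants=len(rows))


def _penalized_point(df: pd.DataFrame, penalty: float) -> float:
    ratios, w = _ratio_inputs(df)
    wm = _weighted_median(ratios, w)
    q_j = w * (ratios - wm) ** 2
    p_j = stats.chi2.sf(q_j, df=1)
    return _weighted_median(ratios, w * np.minimum(1.0, penalty * p_j))


def penalized_weighted_median(
    rows: pd.DataFrame, n_boot: int = 1000, seed: int = 0, penalty: float = 20.0
) -> MREstimate:
    """Weighted median with heterogeneity-penalized weights.

    Each variant's one-df chi-square contribution ``Q_j`` about the plain
    weighted-median estimate is converted to a p-value and the weight is
    multiplied by ``min(1, penalty * p_j)`` (default penalty 20), so only
    clear outliers are down-weighted and homogeneous data reproduce the
    unpenalized estimate.
    """
    rows = _validate(rows, min_rows=3)

    def point(df: pd.DataFrame) -> float:
        return _penalized_point(df, penalty)

    beta = point(rows)
    se = _bootstrap_se(rows, point, n_boot, seed)
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return _estimate(
        "penalized_weighted_median", beta, se, p, n_variants=len(rows)
    )


def all_methods(
    rows: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> list[MREstimate]:
    """IVW, Egger, weighted median, and penalized weighted median on one table."""
    return [
        ivw(rows),
        egger(rows),
        weighted_median(rows, n_boot=n_boot, seed=seed),
        penalized_weighted_median(rows, n_boot=n_boot, seed=seed + 1),
    ]
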