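"""Repeated-simulation calibration studies for the estimators.

Each function runs a self-contained Monte-Carlo experiment against the
synthetic generator and returns summary numbers (mean estimates, rejection
rates, CI coverage). They serve two roles: verification that the estimators
recover known truths under the conditions they were designed for, and a
reproducible record of the package's operating characteristics. All studies
are fully determined by their ``seed``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mr_two_sample as mr2
from .cohort_builder import build_cohort
from .grs import compute_weighted_grs, instrument_strength
from .mr_one_sample import DEFAULT_MR_COVARIATES, two_stage_mr
from .synthetic_cohort import (
    default_variant_panel,
    simulate_cohort,
    simulate_summary_stats,
)
from .types import SimConfig


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31 - 1, size=n)


def estimator_recovery(
    n_seeds: int = 50,
    n_variants: int = 50,
    true_effect: float = 0.2,
    n_exp: int = 300_000,
    n_out: int = 400_000,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean estimate and Monte-Carlo SE per estimator with valid instruments.

    Simulates ``n_seeds`` independent two-sample datasets with no pleiotropy
    and a common causal effect, runs IVW / Egger / WM / PWM on each, and
    summarizes. All four estimators are consistent here, so each mean should
    sit within Monte-Carlo error of the truth.
    """
    panel = default_variant_panel("BMI", n_variants=n_variants, seed=seed)
    estimates: dict[str, list[float]] = {
        "ivw": [],
        "egger": [],
        "weighted_median": [],
        "penalized_weighted_median": [],
    }
    for s in _seeds(seed, n_seeds):
        rows = simulate_summary_stats(
            panel, true_effect, n_exp, n_out, seed=int(s)
        )
        rows = mr2.harmonize(rows)
        for est in mr2.all_methods(rows, n_boot=n_boot, seed=int(s)):
            estimates[est.method].append(est.beta)
    records = []
    for method, vals in estimates.items():
        arr = np.array(vals)
        records.append(
            {
                "method": method,
                "mean_estimate": arr.mean(),
                "mc_se": arr.std(ddof=1) / np.sqrt(len(arr)),
                "true_effect": true_effect,
                "n_seeds": n_seeds,
            }
        )
    return pd.DataFrame(records)


def egger_intercept_type1(
    n_runs: int = 400,
    n_variants: int = 50,
    causal_effect: float = 0.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the Egger intercept test under balanced pleiotropy.

    The pleiotropy effects are mean-zero, so the intercept's null holds and
    the rejection rate should sit at the nominal level. The study panel uses
    effect-allele frequencies in (0.3, 0.7) and pleiotropy SD equal to the
    median outcome SE so the balanced-pleiotropy null is near-homoskedastic
    on the weighted scale the test operates on.
    """
    rng = np.random.default_rng(seed)
    panel = default_variant_panel("BMI", n_variants=n_variants, seed=seed)
    panel = [
        type(p)(
            variant_id=p.variant_id,
            effect_allele=p.effect_allele,
            other_allele=p.other_allele,
            beta=p.beta,
            eaf=float(rng.uniform(0.3, 0.7)),
            trait=p.trait,
        )
        for p in panel
    ]
    n_out = 400_000
    eaf = np.array([p.eaf for p in panel])
    pleio_sd = float(np.median(1.0 / np.sqrt(2 * eaf * (1 - eaf) * n_out)))
    rejections = 0
    for s in _seeds(seed + 1, n_runs):
        rows = simulate_summary_stats(
            panel,
            causal_effect,
            n_exp=300_000,
            n_out=n_out,
            pleiotropy_mode="balanced",
            pleiotropy_sd=pleio_sd,
            seed=int(s),
        )
        est = mr2.egger(mr2.harmonize(rows))
        rejections += est.intercept_p < alpha
    return rejections / n_runs


def weighted_median_robustness(
    n_variants: int = 50,
    invalid_fraction: float = 0.4,
    true_effect: float = 0.2,
    offset: float = 0.02,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Weighted median vs IVW when a minority of instruments is invalid.

    ``invalid_fraction`` of the variants receive a common directional
    pleiotropic offset on the outcome scale (large relative to the outcome
    SEs), displacing IVW while the weighted median — anchored in the valid
    majority of the weight — stays near the truth. The median's consistency
    condition is that *valid instruments carry more than half the weight*,
    so the invalid set is drawn subject to holding less than half of the
    inverse-variance ratio weight (redrawn otherwise); with weights
    proportional to beta_exp^2 a random 40% of variants can otherwise carry
    the majority of the weight by chance.
    """
    if not 0 <= invalid_fraction < 0.5:
        raise ValueError("invalid_fraction must be in [0, 0.5) for consistency")
    panel = default_variant_panel("BMI", n_variants=n_variants, seed=seed)
    rows = simulate_summary_stats(
        panel, true_effect, n_exp=300_000, n_out=400_000, seed=seed + 1
    )
    rng = np.random.default_rng(seed + 2)
    n_invalid = int(round(invalid_fraction * n_variants))
    weight = (rows["beta_exp"] / rows["se_out"]).to_numpy() ** 2
    weight /= weight.sum()
    for _ in range(1000):
        invalid_idx = rng.choice(n_variants, size=n_invalid, replace=False)
        if weight[invalid_idx].sum() < 0.45:
            break
    else:
        raise RuntimeError("could not draw an invalid set below half the weight")
    rows.loc[invalid_idx, "beta_out"] += offset
    rows = mr2.harmonize(rows)
    wm = mr2.weighted_median(rows, n_boot=n_boot, seed=seed + 3)
    ivw_est = mr2.ivw(rows)
    return {
        "wm_estimate": wm.beta,
        "wm_se": wm.se,
        "ivw_estimate": ivw_est.beta,
        "ivw_se": ivw_est.se,
        "true_effect": true_effect,
        "n_invalid": n_invalid,
    }


def two_stage_coverage(
    n_reps: int = 100,
    n: int = 50_000,
    causal_effect: float = 0.3,
    prevalence: float = 0.005,
    seed: int = 0,
) -> dict:
    """95% CI coverage of the two-stage one-sample MR estimate.

    Each replicate simulates a confounded cohort end to end (genotypes,
    registry records), rebuilds case status through the phenotyping rules,
    scores the GRS, and runs the two-stage estimator; coverage is the
    fraction of replicates whose 95% CI contains the true causal log-OR.
    """
    panel = default_variant_panel("BMI", seed=seed)
    covered = 0
    estimates = []
    f_stats = []
    for s in _seeds(seed + 7, n_reps):
        cfg = SimConfig(
            n_participants=n,
            variant_specs=panel,
            causal_effect=causal_effect,
            outcome_baseline_prevalence=prevalence,
            seed=int(s),
        )
        cohort = simulate_cohort(cfg)
        assignment = build_cohort(cohort.participants, cohort.diagnoses)["benign"]
        status = assignment.set_index("participant_id")["status"]
        analysis = cohort.participants.loc[status != "excluded"].copy()
        analysis["case"] = (status.loc[analysis.index] == "benign_case").to_numpy()
        analysis["grs"] = compute_weighted_grs(
            cohort.genotypes.loc[analysis.index], panel
        )["rescaled_score"]
        est = two_stage_mr(
            analysis,
            outcome="case",
            exposure="exposure",
            instrument="grs",
            covariates=DEFAULT_MR_COVARIATES,
        )
        lo, hi = np.log(est.ci95_low), np.log(est.ci95_high)
        covered += lo <= causal_effect <= hi
        estimates.append(est.beta)
        f_stats.append(est.f_stat)
    return {
        "coverage": covered / n_reps,
        "mean_estimate": float(np.mean(estimates)),
        "true_effect": causal_effect,
        "mean_f": float(np.mean(f_stats)),
        "n_reps": n_reps,
        "n": n,
    }


def first_stage_f(n: int = 50_000, seed: int = 0) -> float:
    """First-stage F of the default simulated cohort's GRS on its exposure."""
    panel = default_variant_panel("BMI", seed=seed)
    cfg = SimConfig(n_participants=n, variant_specs=panel, seed=seed)
    cohort = simulate_cohort(cfg)
    scores = compute_weighted_grs(cohort.genotypes, panel)
    covs = cohort.participants[
        [c for c in DEFAULT_MR_COVARIATES if c in cohort.participants.columns]
    ]
    return instrument_strength(
        scores["rescaled_score"], cohort.participants["exposure"], covs
    )
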