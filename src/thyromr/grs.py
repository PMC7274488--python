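"""Weighted genetic risk scores, instrument strength, and liability quartiles.

A participant's raw score is the dosage-weighted sum of per-allele GWAS
effects over the instrument panel; the rescaled score divides by the mean
weight, i.e. multiplies by ``n_variants / sum(weights)``, so one unit equals
one average trait-increasing allele (range 0 to 2*n_variants). Weights must
be oriented to the trait-increasing allele before scoring; ``orient_specs``
flips negative-weight variants (dosage becomes 2 - d, alleles swap).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import VariantSpec, validate_specs
from ._design import build_design


def orient_specs(
    specs: Sequence[VariantSpec], genotypes: pd.DataFrame
) -> tuple[list[VariantSpec], pd.DataFrame]:
    """Orient all weights to the trait-increasing allele.

    Variants with negative weights have beta sign-flipped, alleles swapped,
    effect-allele frequency complemented, and dosages replaced by ``2 - d``.
    The weighted score is unchanged up to an additive constant, which cancels
    in every downstream regression.
    """
    validate_specs(specs)
    geno = genotypes.copy()
    oriented: list[VariantSpec] = []
    for spec in specs:
        if spec.beta < 0:
            oriented.append(
                VariantSpec(
                    variant_id=spec.variant_id,
                    effect_allele=spec.other_allele,
                    other_allele=spec.effect_allele,
                    beta=-spec.beta,
                    eaf=1.0 - spec.eaf,
                    trait=spec.trait,
                )
            )
            geno[spec.variant_id] = 2 - geno[spec.variant_id]
        else:
            oriented.append(spec)
    return oriented, geno


def compute_weighted_grs(
    genotypes: pd.DataFrame, specs: Sequence[VariantSpec]
) -> pd.DataFrame:
    """Per-participant weighted GRS and its allele-count rescaling.

    ``raw_score = sum_j beta_j * dosage_j``;
    ``rescaled_score = raw_score * n_variants / sum_j beta_j``.

    Raises if any panel variant is missing from the dosage matrix or if any
    weight is non-positive (orient first).
    """
    validate_specs(specs)
    missing = [s.variant_id for s in specs if s.variant_id not in genotypes.columns]
    if missing:
        raise KeyError(f"variants absent from genotype matrix: {missing}")
    nonpos = [s.variant_id for s in specs if s.beta <= 0]
    if nonpos:
        raise ValueError(
            f"non-positive weights after orientation for: {nonpos}; "
            "call orient_specs() first"
        )
    betas = np.array([s.beta for s in specs])
    dosages = genotypes[[s.variant_id for s in specs]].to_numpy(dtype=float)
    if np.any(dosages < 0) or np.any(dosages > 2):
        raise ValueError("dosages must lie in [0, 2]")
    raw = dosages @ betas
    rescaled = raw * (len(specs) / betas.sum())
    return pd.DataFrame(
        {
            "trait": specs[0].trait,
            "raw_score": raw,
            "rescaled_score": rescaled,
        },
        index=genotypes.index,
    )


def instrument_strength(
    score: pd.Series | np.ndarray,
    exposure: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> float:
    """First-stage F statistic for the GRS term.

    Linear regression of the continuous exposure on the score (plus
    covariates); returns the squared t statistic of the score coefficient,
    the single-parameter partial F conventionally compared against 10.
    """
    score = np.asarray(score, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if len(score) < 30:
        raise ValueError("need at least 30 participants for a stable F statistic")
    if np.std(score) == 0:
        raise ValueError("constant score: instrument has no variance")
    X = pd.DataFrame({"grs": score})
    if covariates is not None:
        X = pd.concat([X, build_design(covariates.reset_index(drop=True))], axis=1)
    X = sm.add_constant(X)
    fit = sm.OLS(exposure, X).fit()
    return float(fit.tvalues["grs"] ** 2)


def assign_quartiles(scores: pd.Series | np.ndarray) -> pd.Series:
    """Quartile labels 1-4 from the empirical quartiles of the scored population.

    Cut-points are the 25/50/75 percentiles of everyone scored (cases and
    controls together); values exactly at a cut-point go to the lower
    quartile. A degenerate (constant) score distribution raises.
    """
    values = pd.Series(scores).astype(float)
    if len(values) < 4:
        raise ValueError("need at least 4 scored participants")
    if values.nunique() == 1:
        raise ValueError("degenerate score distribution: all scores equal")
    cuts = np.quantile(values.to_numpy(), [0.25, 0.5, 0.75])
    labels = 1 + np.searchsorted(cuts, values.to_numpy(), side="left")
    return pd.Series(labels.astype(int), index=values.index, name="quartile")
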