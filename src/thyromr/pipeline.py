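"""End-to-end orchestration: simulate -> phenotype -> score -> estimate -> report.

A pipeline run is described by a config mapping (usually loaded from YAML)::

    seed: 13
    output_dir: results/demo
    simulate:
      trait: BMI
      n_participants: 20000
      causal_effect: 0.0
      outcome_baseline_prevalence: 0.01
      outcome: benign
    analyses:
      observational: true
      mr_one_sample: true
      mr_two_sample: true
      sensitivity: false
      quartiles: true
    summary_stats:
      causal_effect: 0.0
      n_exp: 300000
      n_out: 400000
      pleiotropy_mode: none

Every stage writes delimited text plus a run log (JSON) recording the seed
and the participant counts surviving each filter, so the exclusion cascade is
auditable. All randomness descends from the single root seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io, reporting
from . import mr_two_sample as mr2
from .cohort_builder import (
    assignment_counts,
    build_cohort,
    sensitivity_exclude_thyroid_dysfunction,
)
from .grs import assign_quartiles, compute_weighted_grs, instrument_strength
from .mr_one_sample import (
    DEFAULT_MR_COVARIATES,
    quartile_association,
    quartile_counts,
    two_stage_mr,
)
from .observational import DEFAULT_COVARIATES, logistic_association
from .synthetic_cohort import (
    default_variant_panel,
    simulate_cohort,
    simulate_summary_stats,
)
from .types import SimConfig

logger = logging.getLogger(__name__)

__version_tag__ = "thyromr-0.1.0"


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "seed" not in cfg:
        raise ValueError("config must set a root seed")
    return cfg


def run_pipeline(config: dict[str, Any], output_dir: str | Path | None = None) -> dict:
    """Run the configured stages; returns the run log (also written to disk)."""
    seed = int(config["seed"])
    outdir = Path(output_dir or config.get("output_dir", "thyromr_results"))
    outdir.mkdir(parents=True, exist_ok=True)
    analyses = config.get("analyses", {})
    run_log: dict[str, Any] = {"version": __version_tag__, "seed": seed, "stages": {}}

    sim_cfg = config.get("simulate", {})
    trait = sim_cfg.get("trait", "BMI")
    stratum = config.get("stratum", "all")

    try:
        panel = default_variant_panel(trait, seed=seed)
        cohort_sim = simulate_cohort(
            SimConfig(
                n_participants=int(sim_cfg.get("n_participants", 20_000)),
                variant_specs=panel,
                causal_effect=float(sim_cfg.get("causal_effect", 0.0)),
                outcome_baseline_prevalence=float(
                    sim_cfg.get("outcome_baseline_prevalence", 0.01)
                ),
                outcome=sim_cfg.get("outcome", "benign"),
                seed=seed,
            )
        )
        io.write_variant_specs(panel, outdir / "variant_weights.tsv")
        io.write_genotypes(cohort_sim.genotypes, outdir / "genotypes.tsv")
        io.write_participants(cohort_sim.participants, outdir / "participants.csv")
        io.write_diagnoses(cohort_sim.diagnoses, outdir / "diagnoses.csv")
        run_log["stages"]["simulate"] = {
            "n_participants": len(cohort_sim.participants),
            "n_variants": len(panel),
            "n_diagnosis_records": len(cohort_sim.diagnoses),
        }
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    # --- cohort build ------------------------------------------------------
    try:
        assignments = build_cohort(
            cohort_sim.participants,
            cohort_sim.diagnoses,
            window_months=float(config.get("window_months", 12)),
        )
        outcome = sim_cfg.get("outcome", "benign")
        assignment = assignments[outcome]
        if analyses.get("sensitivity", False):
            io.write_assignment(assignment, outdir / f"assignment_{outcome}_primary.csv")
            assignment = sensitivity_exclude_thyroid_dysfunction(
                assignment, cohort_sim.diagnoses
            )
        io.write_assignment(assignment, outdir / f"assignment_{outcome}.csv")
        run_log["stages"]["cohort"] = assignment_counts(assignment)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage 'cohort' failed: {e}") from e

    # --- analysis table ----------------------------------------------------
    status = assignment.set_index("participant_id")["status"]
    data = cohort_sim.participants.loc[status != "excluded"].copy()
    data["case"] = (status.loc[data.index] == f"{outcome}_case").to_numpy()
    data["t2dm"] = assignments["t2dm"].loc[data.index]

    # --- GRS ---------------------------------------------------------------
    try:
        scores = compute_weighted_grs(cohort_sim.genotypes.loc[data.index], panel)
        data["grs"] = scores["rescaled_score"]
        data["quartile"] = assign_quartiles(data["grs"])
        covs = data[[c for c in DEFAULT_MR_COVARIATES if c in data.columns]]
        f_stat = instrument_strength(data["grs"], data["exposure"], covs)
        scores.join(data["quartile"]).to_csv(
            outdir / "grs_profiles.csv", index_label="participant_id"
        )
        run_log["stages"]["grs"] = {"n_scored": len(scores), "first_stage_f": f_stat}
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage 'grs' failed: {e}") from e

    # --- observational -----------------------------------------------------
    if analyses.get("observational", True):
        try:
            results = []
            trait_col = trait.lower() if trait.lower() in data.columns else "exposure"
            trait_cols = [trait_col] + [
                c for c in ("hdl", "ldl", "tg", "glucose") if c != trait_col
            ]
            for col in trait_cols:
                if col not in data.columns:
                    continue
                results.append(
                    logistic_association(
                        data, "case", col, DEFAULT_COVARIATES, stratum=stratum
                    )
                )
            table = reporting.format_observational_table(results)
            table.to_csv(outdir / "observational.csv", index=False)
            run_log["stages"]["observational"] = {"n_models": len(results)}
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"stage 'observational' failed: {e}") from e

    # --- one-sample MR -----------------------------------------------------
    if analyses.get("mr_one_sample", True):
        try:
            est = two_stage_mr(
                data, "case", "exposure", "grs", covariates=DEFAULT_MR_COVARIATES
            )
            pd.DataFrame(
                [
                    {
                        "method": est.method,
                        "or": est.odds_ratio,
                        "ci95_low": est.ci95_low,
                        "ci95_high": est.ci95_high,
                        "p": est.p,
                        "f_stat": est.f_stat,
                        "n": est.n_participants,
                    }
                ]
            ).to_csv(outdir / "mr_one_sample.csv", index=False)
            run_log["stages"]["mr_one_sample"] = {
                "estimate_log_or": est.beta,
                "first_stage_f": est.f_stat,
            }
            if analyses.get("quartiles", True):
                counts = quartile_counts(data, "case")
                adj = quartile_association(data, "case")
                reporting.format_quartile_table(counts, adj).to_csv(
                    outdir / "mr_quartiles.csv", index=False
                )
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"stage 'mr_one_sample' failed: {e}") from e

    # --- two-sample MR -----------------------------------------------------
    if analyses.get("mr_two_sample", True):
        try:
            ss_cfg = config.get("summary_stats", {})
            rows = simulate_summary_stats(
                panel,
                causal_effect=float(ss_cfg.get("causal_effect", 0.0)),
                n_exp=int(ss_cfg.get("n_exp", 300_000)),
                n_out=int(ss_cfg.get("n_out", 400_000)),
                pleiotropy_mode=ss_cfg.get("pleiotropy_mode", "none"),
                pleiotropy_mean=float(ss_cfg.get("pleiotropy_mean", 0.0)),
                pleiotropy_sd=float(ss_cfg.get("pleiotropy_sd", 0.0)),
                seed=seed + 1,
            )
            io.write_summary_stats(rows, outdir / "summary_stats.tsv")
            harmonized = mr2.harmonize(rows)
            results = mr2.all_methods(harmonized, seed=seed + 2)
            reporting.format_two_sample_table({trait: results}).to_csv(
                outdir / "mr_two_sample.csv", index=False
            )
            run_log["stages"]["mr_two_sample"] = {
                e.method: e.beta for e in results
            }
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"stage 'mr_two_sample' failed: {e}") from e

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=float)
    logger.info("pipeline complete: %s", outdir)
    return run_log
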