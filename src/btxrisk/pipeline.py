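"""End-to-end orchestration: synthetic cohort (or CSV inputs) through
exposure metrics, damage endpoints, association models, WQS mixture
regression, dose grouping, benchmark-dose estimation and REL derivation.

Every stage persists its table under the output directory, so each number
in the summary report is re-derivable from the stage CSVs.  A single
master seed drives all stage-specific randomness deterministically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations, bmd, cohort, exposure, hematology, wqs

logger = logging.getLogger(__name__)

ANALYTES = cohort.ANALYTES

COVARIATE_COLUMNS = ["age", "bmi", "smoker", "pack_years", "drinker", "factory_guangzhou"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    output_dir: str = "btxrisk_run"
    seed: int = 0
    cohort_spec: cohort.CohortSpec | None = None
    workers_csv: str | None = None
    hemograms_csv: str | None = None
    exposure_csv: str | None = None
    bmr: float = 0.10
    confidence: float = 0.95
    working_years: float = 40.0
    wqs_bootstrap: int = 100
    wqs_train_fraction: float = 0.4
    n_dose_groups: int = 8
    dose_group_min_n: int = 70
    dose_group_max_n: int = 200
    wqs_outcomes: tuple[str, ...] = ("monocytes", "lymphocytes", "hematocrit")
    reference_limits: hematology.ReferenceLimits = field(default_factory=hematology.ReferenceLimits)

    def __post_init__(self) -> None:
        if not (0 < self.bmr < 1):
            raise ValueError(f"BMR must be in (0, 1), got {self.bmr}")
        has_csv = self.workers_csv is not None
        if (self.cohort_spec is None) == (not has_csv):
            raise ValueError("exactly one of cohort_spec or CSV input paths must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec_raw = raw.pop("cohort_spec", None)
        spec = None
        if spec_raw is not None:
            if "ce_rank_correlation" in spec_raw:
                spec_raw["ce_rank_correlation"] = np.asarray(spec_raw["ce_rank_correlation"], float)
            for key in ("decline_effect_beta",):
                if key in spec_raw:
                    spec_raw[key] = {tuple(k.split(":")): v for k, v in spec_raw[key].items()}
            spec = cohort.CohortSpec(**spec_raw)
        return cls(cohort_spec=spec, **raw)


def _stage(report: dict, name: str, t0: float, **info) -> None:
    elapsed = time.perf_counter() - t0
    logger.info("stage %-12s %s elapsed=%.2fs", name, info, elapsed)
    report["stages"].append({"stage": name, "elapsed_s": round(elapsed, 3), **info})


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and persist) the summary report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    # --- inputs -----------------------------------------------------------
    t0 = time.perf_counter()
    if config.cohort_spec is not None:
        spec = config.cohort_spec
        workers, hemo, expo = cohort.generate_cohort(spec)
        report["true_bmd"] = spec.true_bmd(config.bmr)
    else:
        workers = pd.read_csv(config.workers_csv)
        hemo = pd.read_csv(config.hemograms_csv)
        expo = pd.read_csv(config.exposure_csv)
    workers.to_csv(out / "workers.csv", index=False)
    hemo.to_csv(out / "hemograms.csv", index=False)
    expo.to_csv(out / "exposure.csv", index=False)
    _stage(report, "inputs", t0, n_workers=len(workers))

    # --- exposure metrics -------------------------------------------------
    t0 = time.perf_counter()
    for a in ANALYTES:
        expo[f"quartile_{a}"] = exposure.quantile_score(expo[f"ce_{a}"], q=4)
    expo.to_csv(out / "exposure.csv", index=False)
    _stage(report, "exposure", t0, n_rows=len(expo))

    # --- endpoints --------------------------------------------------------
    t0 = time.perf_counter()
    declines = hemo[["worker_id"] + [f"decline_{p}" for p in hematology.PARAMETERS]]
    calls = hematology.classify_damage(
        hemo, declines, workers["sex"], limits=config.reference_limits
    )
    calls.to_csv(out / "damage_calls.csv", index=False)
    incidence = float(calls["is_case"].mean())
    _stage(report, "endpoints", t0, cases=int(calls["is_case"].sum()), incidence=round(incidence, 4))
    report["damage_incidence"] = incidence

    # --- association models ----------------------------------------------
    t0 = time.perf_counter()
    cov = workers[COVARIATE_COLUMNS].copy()
    assoc_rows = []
    for p in hematology.PARAMETERS:
        base_col = f"baseline_{p}"
        cov_p = cov.copy()
        cov_p[base_col] = hemo[base_col].to_numpy()
        cov_p["sex_male"] = (workers["sex"] == "male").astype(float).to_numpy()
        mean_dec, tstat, pval = associations.paired_change_test(hemo[f"baseline_{p}"], hemo[f"followup_{p}"])
        for a in ANALYTES:
            res = associations.adjusted_decline_model(
                hemo[f"decline_{p}"], expo[f"ln_ce_{a}"], cov_p, outcome=p, analyte=a
            )
            assoc_rows.append(
                {
                    "outcome": p, "analyte": a, "beta": res.beta,
                    "ci_low": res.ci95[0], "ci_high": res.ci95[1], "p_trend": res.p_trend,
                    "mean_decline": mean_dec, "paired_t": tstat, "paired_p": pval,
                }
            )
    assoc = pd.DataFrame(assoc_rows)
    assoc.to_csv(out / "associations.csv", index=False)
    _stage(report, "associate", t0, n_models=len(assoc))

    # --- WQS --------------------------------------------------------------
    t0 = time.perf_counter()
    wqs_rows = []
    scores = np.column_stack([expo[f"quartile_{a}"].to_numpy(float) for a in ANALYTES])
    for p in config.wqs_outcomes:
        cov_p = cov.copy()
        cov_p["sex_male"] = (workers["sex"] == "male").astype(float).to_numpy()
        cov_p[f"baseline_{p}"] = hemo[f"baseline_{p}"].to_numpy()
        fit = wqs.run_wqs(
            scores, hemo[f"decline_{p}"].to_numpy(), cov_p.to_numpy(float),
            n_bootstrap=config.wqs_bootstrap, train_fraction=config.wqs_train_fraction,
            seed=config.seed, outcome_name=p,
        )
        wqs_rows.append(
            {
                "outcome": p, "beta": fit.beta, "ci_low": fit.ci95[0], "ci_high": fit.ci95[1],
                "p_trend": fit.p_trend,
                **{f"w_{a}": fit.weights[i] for i, a in enumerate(ANALYTES)},
                "n_bootstrap": fit.n_bootstrap, "seed": fit.seed,
            }
        )
    wqs_table = pd.DataFrame(wqs_rows)
    wqs_table.to_csv(out / "wqs.csv", index=False)
    _stage(report, "wqs", t0, n_outcomes=len(wqs_table))

    # --- dose groups + BMD suite -----------------------------------------
    t0 = time.perf_counter()
    cases = calls["is_case"].to_numpy(int)
    bmd_rows, group_frames = [], []
    report["bmd"] = {}
    for a in ANALYTES:
        groups = exposure.assign_dose_groups(
            expo[f"ce_{a}"].to_numpy(), cases, analyte=a,
            n_groups=config.n_dose_groups, min_n=config.dose_group_min_n,
            max_n=config.dose_group_max_n,
        )
        group_frames.append(exposure.dose_groups_frame(groups))
        fits = bmd.fit_suite(groups, bmr=config.bmr, confidence=config.confidence, seed=config.seed)
        for f in fits:
            bmd_rows.append(
                {
                    "analyte": a, "family": f.family, "loglik": f.loglik, "aic": f.aic,
                    "gof_chi2": f.gof_chi2, "gof_df": f.gof_df, "gof_p": f.gof_p,
                    "bmd": f.bmd, "bmdl": f.bmdl, "converged": f.converged,
                }
            )
        best = bmd.select_best(fits, groups)
        if best is None:
            report["bmd"][a] = {"model": None, "note": "no adequate model"}
        else:
            rel = bmd.derive_rel(best.bmdl, analyte=a, working_years=config.working_years)
            report["bmd"][a] = {
                "model": best.family, "aic": best.aic, "gof_p": best.gof_p,
                "bmd": best.bmd, "bmdl": best.bmdl,
                "rel_mgm3": rel.rel_mgm3, "rel_ppm": rel.rel_ppm,
            }
    pd.concat(group_frames).to_csv(out / "dose_groups.csv", index=False)
    pd.DataFrame(bmd_rows).to_csv(out / "bmd_fits.csv", index=False)
    _stage(report, "bmd", t0, n_fits=len(bmd_rows))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
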