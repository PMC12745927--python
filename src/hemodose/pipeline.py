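"""End-to-end orchestration: per-patient simulation and cohort analysis.

``run_patient`` turns one patient's dose grid, compartment masks, plan
metadata and sex into a single metrics row (dynamic blood metrics, static
comparators, per-compartment DVH doses).  ``run_cohort`` maps that over a
cohort directory, joins the rows with the covariate/outcome table, and
runs the statistical stage (quartile log-rank, Cox models per endpoint,
Kaplan–Meier coordinates, compartment relevance), writing tidy CSV outputs
plus a JSON-lines run log.  Per-patient failures are logged and skipped,
never fatal to the cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .anatomy import DoseGrid, LabelMap, build_patient_model, default_physiology
from .circulation import CirculationParams
from .delivery import build_schedule, score_course
from .io import (
    load_coverage_table,
    load_dose,
    load_edic_coefficients,
    load_mask,
    load_physiology_table,
    load_plan,
)
from .metrics import (
    DEFAULT_X_LEVELS,
    DEFAULT_Y_LEVELS,
    compartment_dvh_metric,
    compute_metrics,
    edic,
    static_body_dose,
    static_hedos_dose,
)
from .relevance import compartment_relevance
from .survival import adjust_pvalues, cox_fit, kaplan_meier, ph_check, quartile_logrank

__all__ = ["RunConfig", "CohortResult", "run_patient", "run_cohort"]

EDIC_ORGANS = ("lungs", "heart", "liver")


@dataclass(frozen=True)
class RunConfig:
    """Knobs of a pipeline run; every random draw traces back to ``seed``."""

    seed: int = 0
    n_particles: int = 10_000
    dose_rate_gy_min: float = 3.0
    beam_off_gap_s: float = 10.0
    x_levels: tuple[float, ...] = DEFAULT_X_LEVELS
    y_levels: tuple[float, ...] = DEFAULT_Y_LEVELS
    dose_covariate: str = "d90_blood"
    covariates: tuple[str, ...] = ("age", "stage", "prescription_gy")
    categorical: tuple[str, ...] = ("smoking",)
    physiology_table: str | None = None
    coverage_table: str | None = None
    edic_table: str | None = None


def run_patient(
    config: RunConfig,
    dose: DoseGrid,
    masks: Mapping[str, LabelMap],
    plan_meta: Mapping[str, Any],
    sex: str,
    seed: int | None = None,
) -> dict[str, Any]:
    """Simulate one patient and return a flat metrics row.

    The row holds the dynamic blood metrics (``d_mean``, ``d_<X>pct``,
    ``v_<Y>gy`` plus the ``d90_blood`` alias used by the analysis stage),
    the static comparators (body mean and integral dose, mean dose over
    the compartment union, EDIC or None), and DVH D_90 per compartment.
    """
    physiology_table = load_physiology_table(config.physiology_table)
    coverage_table = load_coverage_table(config.coverage_table)
    model = build_patient_model(
        dose, masks, default_physiology(sex), physiology_table, coverage_table
    )
    schedule = build_schedule(
        plan_meta,
        dose_rate_gy_min=config.dose_rate_gy_min,
        beam_off_gap_s=config.beam_off_gap_s,
    )
    params = CirculationParams(
        n_particles=config.n_particles,
        rng_seed=config.seed if seed is None else seed,
    )
    distribution = score_course(model, params, schedule)
    metrics = compute_metrics(distribution, config.x_levels, config.y_levels)

    row: dict[str, Any] = dict(metrics.as_row())
    if 90.0 in metrics.d_x:
        row["d90_blood"] = metrics.d_x[90.0]

    body = LabelMap(mask=np.ones(dose.shape, dtype=bool), name="body")
    if "body" in masks:
        body = masks["body"]
    body_dose = static_body_dose(dose, body)
    row["d_static_body"] = body_dose.mean_gy
    row["d_static_body_integral_gy_l"] = body_dose.integral_gy_l
    row["d_static_hedos"] = static_hedos_dose(dose, list(masks.values()))

    organ_means = {
        organ: float(dose.values[masks[organ].mask].mean()) if organ in masks else None
        for organ in EDIC_ORGANS
    }
    row["edic"] = edic(
        organ_means["lungs"],
        organ_means["heart"],
        organ_means["liver"],
        body_dose.mean_gy,
        schedule.n_fractions,
        load_edic_coefficients(config.edic_table),
    )

    for compartment in model.compartments:
        row[f"d90_{compartment.name}"] = compartment_dvh_metric(compartment, 90.0)
    row["seed"] = params.rng_seed
    row["n_particles"] = params.n_particles
    return row


@dataclass
class CohortResult:
    """In-memory bundle of everything ``run_cohort`` computed and wrote."""

    metrics: pd.DataFrame
    merged: pd.DataFrame
    cox_results: pd.DataFrame
    logrank_results: pd.DataFrame
    km_curves: pd.DataFrame
    relevance: pd.DataFrame
    log: list[dict[str, Any]] = field(default_factory=list)
    out_dir: Path | None = None


def _endpoints_in(table: pd.DataFrame) -> list[str]:
    endpoints = []
    for column in table.columns:
        if column.startswith("time_"):
            name = column[len("time_"):]
            if f"event_{name}" in table.columns:
                endpoints.append(name)
    return endpoints


def _analyze(
    config: RunConfig, merged: pd.DataFrame, log: list[dict[str, Any]]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cox, quartile log-rank and KM coordinates for every endpoint."""
    cox_rows: list[dict[str, Any]] = []
    logrank_rows: list[dict[str, Any]] = []
    km_rows: list[pd.DataFrame] = []
    covariates = [c for c in config.covariates if c in merged.columns]
    categorical = [c for c in config.categorical if c in merged.columns]
    dose_col = config.dose_covariate

    for endpoint in _endpoints_in(merged):
        time_col, event_col = f"time_{endpoint}", f"event_{endpoint}"
        curve = kaplan_meier(merged[time_col], merged[event_col])
        km = curve.as_frame()
        km.insert(0, "endpoint", endpoint)
        km_rows.append(km)

        if dose_col in merged.columns:
            try:
                statistic, p = quartile_logrank(
                    merged[dose_col], merged[time_col], merged[event_col]
                )
                logrank_rows.append(
                    {
                        "endpoint": endpoint,
                        "metric": dose_col,
                        "statistic": statistic,
                        "p": p,
                    }
                )
            except ValueError as err:
                log.append({"event": "logrank_skipped", "endpoint": endpoint, "reason": str(err)})

        model_covariates = covariates + categorical
        if dose_col in merged.columns:
            model_covariates = model_covariates + [dose_col]
        try:
            fit = cox_fit(
                merged, time_col, event_col, model_covariates, categorical=categorical
            )
        except ValueError as err:
            log.append({"event": "cox_skipped", "endpoint": endpoint, "reason": str(err)})
            continue
        ph = ph_check(fit)
        for term, stats_row in fit.summary.iterrows():
            cox_rows.append(
                {
                    "endpoint": endpoint,
                    "covariate": term,
                    "coef": stats_row["coef"],
                    "hr": stats_row["hr"],
                    "ci_lower": stats_row["ci_lower"],
                    "ci_upper": stats_row["ci_upper"],
                    "p": stats_row["p"],
                    "ph_p": ph.get(term, np.nan),
                    "n_used": fit.n_used,
                    "n_events": fit.n_events,
                    "converged": fit.converged,
                }
            )
        log.append(
            {
                "event": "cox_fit",
                "endpoint": endpoint,
                "n_used": fit.n_used,
                "n_events": fit.n_events,
                "n_excluded": fit.n_excluded,
                "converged": fit.converged,
            }
        )

    cox = pd.DataFrame(cox_rows)
    if not cox.empty:
        adjusted = np.full(len(cox), np.nan)
        valid = cox["p"].notna().to_numpy()
        if valid.any():
            adjusted[valid] = adjust_pvalues(cox.loc[valid, "p"].to_numpy(), "holm")
        cox["p_holm"] = adjusted
    logrank = pd.DataFrame(logrank_rows)
    km_curves = (
        pd.concat(km_rows, ignore_index=True)
        if km_rows
        else pd.DataFrame(columns=["endpoint", "time", "survival"])
    )
    return cox, logrank, km_curves


def _relevance_table(merged: pd.DataFrame, dose_col: str) -> pd.DataFrame:
    compartment_cols = [
        c for c in merged.columns if c.startswith("d90_") and c != dose_col and c != "d90_blood"
    ]
    if not compartment_cols or dose_col not in merged.columns:
        return pd.DataFrame(columns=["compartment", "n", "r", "p"])
    long = merged.melt(
        id_vars=[dose_col],
        value_vars=compartment_cols,
        var_name="compartment",
        value_name="d90_compartment",
    )
    long["compartment"] = long["compartment"].str.removeprefix("d90_")
    return compartment_relevance(
        long, blood_dose_col=dose_col, compartment_dose_col="d90_compartment"
    )


def run_cohort(
    config: RunConfig,
    cohort_dir: str | Path,
    out_dir: str | Path | None = None,
) -> CohortResult:
    """Run the whole pipeline over a cohort directory.

    Expects the layout written by ``hemodose synth``: ``cohort.csv`` with
    covariates and per-endpoint outcomes, and ``patients/<id>/`` holding
    ``dose.nii.gz``, ``plan.json``, ``meta.json`` (sex) and
    ``masks/<name>.nii.gz``.  Patients with missing files are skipped with
    a logged reason.  The survival stage is skipped (with a warning) when
    fewer than two analyzable patients remain.
    """
    cohort_dir = Path(cohort_dir)
    log: list[dict[str, Any]] = [{"event": "run_started", "seed": config.seed}]
    cohort = pd.read_csv(cohort_dir / "cohort.csv")
    children = np.random.SeedSequence(config.seed).spawn(len(cohort))

    rows = []
    for (_, patient), child in zip(cohort.iterrows(), children):
        pid = str(patient["patient_id"])
        pdir = cohort_dir / "patients" / pid
        try:
            dose = load_dose(pdir / "dose.nii.gz")
            plan_meta = load_plan(pdir / "plan.json")
            meta = json.loads((pdir / "meta.json").read_text())
            masks = {
                p.name.split(".")[0]: load_mask(p, grid=dose)
                for p in sorted((pdir / "masks").glob("*.nii.gz"))
            }
            if not masks:
                raise FileNotFoundError(f"no masks under {pdir / 'masks'}")
            row = run_patient(
                config,
                dose,
                masks,
                plan_meta,
                meta["sex"],
                seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
            )
        except (FileNotFoundError, KeyError, ValueError) as err:
            log.append({"event": "patient_skipped", "patient_id": pid, "reason": str(err)})
            continue
        row["patient_id"] = pid
        rows.append(row)

    if not rows:
        raise RuntimeError("no analyzable patients in cohort")
    metrics = pd.DataFrame(rows)
    merged = cohort.merge(metrics, on="patient_id", how="inner", suffixes=("_cohort", ""))
    log.append({"event": "patients_analyzed", "n": len(metrics), "n_total": len(cohort)})

    if len(merged) >= 2:
        cox, logrank, km_curves = _analyze(config, merged, log)
    else:
        warnings.warn("fewer than 2 analyzable patients; survival stage skipped", stacklevel=2)
        log.append({"event": "survival_skipped", "reason": "fewer than 2 analyzable patients"})
        cox = pd.DataFrame()
        logrank = pd.DataFrame()
        km_curves = pd.DataFrame(columns=["endpoint", "time", "survival"])
    relevance = _relevance_table(merged, config.dose_covariate)

    result = CohortResult(
        metrics=metrics,
        merged=merged,
        cox_results=cox,
        logrank_results=logrank,
        km_curves=km_curves,
        relevance=relevance,
        log=log,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        merged.to_csv(out / "cohort_metrics.csv", index=False)
        cox.to_csv(out / "cox_results.csv", index=False)
        logrank.to_csv(out / "logrank_results.csv", index=False)
        km_curves.to_csv(out / "km_curves.csv", index=False)
        relevance.to_csv(out / "relevance.csv", index=False)
        with open(out / "run_log.jsonl", "w") as handle:
            for entry in log:
                handle.write(json.dumps(entry) + "\n")
        result.out_dir = out
    return result
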