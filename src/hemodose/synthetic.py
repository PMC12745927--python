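"""Synthetic phantoms and outcome-bearing cohorts.

Real inputs to the pipeline are a planning dose grid, compartment label
maps, plan metadata and a censored time-to-event table.  This module
generates all of them with the statistical structure the analysis assumes,
so every stage is exercisable at desk scale:

* phantoms: a small 3D grid with geometric compartments (spheres, boxes,
  tubes), a spherical target, and a dose field built from a Gaussian
  fall-off around the target plus a Gaussian beam track, normalised so the
  target mean equals the prescription;
* cohorts: site templates (head-and-neck-like, brain-like, lung-like)
  placing different compartments near the target, per-patient jitter of
  geometry and prescription, and event times drawn from an exponential
  baseline hazard with a log-linear dependence on the blood D_90% (and
  optionally other covariates), with independent exponential censoring
  calibrated so every patient's censoring probability equals the requested
  rate exactly.

Event times come from the closed-form inverse transform of the exponential
model, so the generator itself is oracle-checkable; declared log-hazard
coefficients are returned as ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .anatomy import DoseGrid, LabelMap, build_patient_model, default_physiology
from .circulation import CirculationParams
from .delivery import build_schedule, score_course
from .io import load_coverage_table, load_physiology_table
from .metrics import compartment_dvh_metric, compute_metrics

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "simulate_cohort",
    "sample_patient",
    "site_template",
    "SITE_TEMPLATES",
]

# Geometry primitives are plain dicts:
#   {"kind": "sphere", "center_mm": (z, y, x), "radius_mm": r}
#   {"kind": "box", "lo_mm": (z, y, x), "hi_mm": (z, y, x)}
#   {"kind": "tube", "axis": 0|1|2, "center_mm": (z, y, x),
#    "radius_mm": r, "half_length_mm": L}

SITE_TEMPLATES: dict[str, dict[str, Any]] = {
    # Head-and-neck-like: large vessels run right past the target.
    "hnscc": {
        "target_center_mm": (60.0, 60.0, 60.0),
        "target_radius_mm": 14.0,
        "beam_axis": 1,
        "compartments": {
            "large_arteries": {
                "kind": "tube", "axis": 0, "center_mm": (60.0, 72.0, 60.0),
                "radius_mm": 5.0, "half_length_mm": 45.0,
            },
            "large_veins": {
                "kind": "tube", "axis": 0, "center_mm": (60.0, 48.0, 60.0),
                "radius_mm": 5.0, "half_length_mm": 45.0,
            },
            "brain": {"kind": "sphere", "center_mm": (15.0, 60.0, 60.0), "radius_mm": 18.0},
            "skeletal_muscle": {
                "kind": "box", "lo_mm": (95.0, 0.0, 0.0), "hi_mm": (119.0, 119.0, 119.0),
            },
        },
    },
    # Brain-like: target sits inside the brain; everything else is distant.
    "gbm": {
        "target_center_mm": (45.0, 70.0, 70.0),
        "target_radius_mm": 12.0,
        "beam_axis": 1,
        "compartments": {
            "brain": {"kind": "sphere", "center_mm": (45.0, 60.0, 60.0), "radius_mm": 30.0},
            "large_arteries": {
                "kind": "tube", "axis": 0, "center_mm": (100.0, 30.0, 30.0),
                "radius_mm": 5.0, "half_length_mm": 18.0,
            },
            "skeletal_muscle": {
                "kind": "box", "lo_mm": (100.0, 60.0, 0.0), "hi_mm": (119.0, 119.0, 119.0),
            },
        },
    },
    # Lung-like: target in a lung adjacent to the heart; liver inferior.
    "nsclc": {
        "target_center_mm": (62.0, 60.0, 38.0),
        "target_radius_mm": 13.0,
        "beam_axis": 1,
        "compartments": {
            "lungs": {"kind": "box", "lo_mm": (40.0, 20.0, 12.0), "hi_mm": (88.0, 100.0, 52.0)},
            "heart": {"kind": "sphere", "center_mm": (64.0, 60.0, 62.0), "radius_mm": 14.0},
            "liver": {"kind": "box", "lo_mm": (96.0, 40.0, 40.0), "hi_mm": (118.0, 100.0, 100.0)},
        },
    },
    # One irradiated compartment (heart at the target), all others cold and
    # away from the beam track: used for relevance sanity checks.
    "isolated": {
        "target_center_mm": (60.0, 60.0, 60.0),
        "target_radius_mm": 14.0,
        "beam_axis": 1,
        "compartments": {
            "heart": {"kind": "sphere", "center_mm": (60.0, 60.0, 60.0), "radius_mm": 14.0},
            "brain": {"kind": "sphere", "center_mm": (12.0, 60.0, 14.0), "radius_mm": 10.0},
            "liver": {"kind": "box", "lo_mm": (104.0, 0.0, 0.0), "hi_mm": (119.0, 119.0, 30.0)},
        },
    },
}

#: Per-site prescription distribution (mean, sd) in Gy, matching the cohort
#: descriptors the generator emulates.
SITE_PRESCRIPTION_GY = {
    "hnscc": (68.7, 2.7),
    "gbm": (59.8, 8.8),
    "nsclc": (66.1, 6.9),
    "isolated": (60.0, 8.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, beam and plan parameters of one synthetic patient."""

    shape: tuple[int, int, int] = (24, 24, 24)
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    compartments: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    target_center_mm: tuple[float, float, float] = (60.0, 60.0, 60.0)
    target_radius_mm: float = 14.0
    beam_axis: int = 1
    penumbra_mm: float = 8.0
    track_weight: float = 0.25
    prescription_gy: float = 60.0
    n_fractions: int = 30
    fields_per_fraction: int = 1
    dose_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prescription_gy < 0:
            raise ValueError("prescription must be non-negative")
        if self.penumbra_mm <= 0 or self.target_radius_mm <= 0:
            raise ValueError("penumbra and target radius must be positive")


def _coordinate_grids(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing_mm)]
    return np.meshgrid(*axes, indexing="ij")


def _primitive_mask(primitive: Mapping[str, Any], grids: tuple[np.ndarray, ...]) -> np.ndarray:
    kind = primitive["kind"]
    if kind == "sphere":
        center = primitive["center_mm"]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        return d2 <= primitive["radius_mm"] ** 2
    if kind == "box":
        lo, hi = primitive["lo_mm"], primitive["hi_mm"]
        inside = np.ones(grids[0].shape, dtype=bool)
        for g, a, b in zip(grids, lo, hi):
            inside &= (g >= a) & (g <= b)
        return inside
    if kind == "tube":
        axis = primitive["axis"]
        center = primitive["center_mm"]
        perp2 = sum((g - c) ** 2 for i, (g, c) in enumerate(zip(grids, center)) if i != axis)
        along = np.abs(grids[axis] - center[axis])
        return (perp2 <= primitive["radius_mm"] ** 2) & (along <= primitive["half_length_mm"])
    raise ValueError(f"unknown primitive kind {kind!r}")


def make_phantom(spec: PhantomSpec) -> tuple[DoseGrid, dict[str, LabelMap], dict[str, Any]]:
    """Build (dose grid, compartment masks, plan metadata) from a spec.

    The dose field is a Gaussian fall-off beyond the spherical target
    (width ``penumbra_mm``) superposed with a Gaussian beam track along
    ``beam_axis``, normalised so the mean dose inside the target equals
    the prescription.  A zero prescription yields an all-zero grid.
    """
    extent = [(n - 1) * s for n, s in zip(spec.shape, spec.spacing_mm)]
    for c, e in zip(spec.target_center_mm, extent):
        if not (0.0 <= c <= e):
            raise ValueError(f"target centre {spec.target_center_mm} outside grid extent {extent}")
    grids = _coordinate_grids(spec)

    masks = {
        name: LabelMap(mask=_primitive_mask(primitive, grids), name=name)
        for name, primitive in spec.compartments.items()
    }

    target = {
        "kind": "sphere",
        "center_mm": spec.target_center_mm,
        "radius_mm": spec.target_radius_mm,
    }
    target_mask = _primitive_mask(target, grids)
    if not target_mask.any():
        raise ValueError("target sphere contains no voxels")

    distance = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, spec.target_center_mm)))
    excess = np.clip(distance - spec.target_radius_mm, 0.0, None)
    falloff = np.exp(-(excess**2) / (2.0 * spec.penumbra_mm**2))
    perp2 = sum(
        (g - c) ** 2
        for i, (g, c) in enumerate(zip(grids, spec.target_center_mm))
        if i != spec.beam_axis
    )
    sigma_track = 0.8 * spec.target_radius_mm
    track = np.exp(-perp2 / (2.0 * sigma_track**2))
    raw = falloff + spec.track_weight * track
    if spec.dose_noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log1p(spec.dose_noise_cv**2))
        raw = raw * rng.lognormal(-0.5 * sigma**2, sigma, size=raw.shape)
    dose_values = raw * (spec.prescription_gy / raw[target_mask].mean())

    dose = DoseGrid(values=dose_values, spacing=spec.spacing_mm)
    plan_meta = {
        "n_fractions": spec.n_fractions,
        "prescription_gy": spec.prescription_gy,
        "fields_per_fraction": spec.fields_per_fraction,
    }
    return dose, masks, plan_meta


def site_template(site: str) -> dict[str, Any]:
    try:
        return SITE_TEMPLATES[site]
    except KeyError:
        raise ValueError(f"unknown site {site!r}; expected one of {sorted(SITE_TEMPLATES)}") from None


@dataclass(frozen=True)
class CohortSpec:
    """Conditions under which a synthetic cohort is generated.

    ``betas`` are true log-hazard coefficients per unit of the named
    numeric column (per Gy for ``d90_blood``); event times are exponential
    with rate ``baseline_hazard_per_day * exp(sum(beta * x))`` and
    censoring is an independent exponential calibrated so P(censored) =
    ``censoring_rate`` for every patient.  ``dose_mode`` selects between
    the full phantom + particle-transport pipeline (``"simulate"``) and a
    fast surrogate that draws blood D_90% from a truncated normal
    (``"surrogate"``) for statistics-only studies.
    """

    n_patients: int = 100
    site: str = "hnscc"
    dose_mode: str = "simulate"
    n_particles: int = 2000
    endpoints: tuple[str, ...] = ("OS",)
    baseline_hazard_per_day: float = 1.0 / 1000.0
    betas: Mapping[str, float] = field(default_factory=lambda: {"d90_blood": 0.2})
    censoring_rate: float = 0.3
    dose_mean_gy: float = 3.0
    dose_sd_gy: float = 1.5
    p_male: float = 0.6
    template: Mapping[str, Any] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.baseline_hazard_per_day <= 0:
            raise ValueError("baseline hazard must be positive")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.dose_mode not in ("simulate", "surrogate"):
            raise ValueError("dose_mode must be 'simulate' or 'surrogate'")


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> dict[str, Any]:
    rx_mean, rx_sd = SITE_PRESCRIPTION_GY.get(spec.site, (60.0, 8.0))
    prescription = float(np.clip(rng.normal(rx_mean, rx_sd), 20.0, 80.0))
    return {
        "sex": "male" if rng.random() < spec.p_male else "female",
        "age": float(np.clip(rng.normal(60.0, 10.0), 25.0, 90.0)),
        "smoking": rng.choice(["never", "former", "current"], p=[0.3, 0.4, 0.3]),
        "stage": int(rng.choice([1, 2, 3, 4], p=[0.05, 0.15, 0.40, 0.40])),
        "prescription_gy": prescription,
        "n_fractions": int(max(1, round(prescription / 2.0))),
    }


def sample_patient(
    spec: CohortSpec, index: int, rng: np.random.Generator
) -> tuple[dict[str, Any], PhantomSpec]:
    """Covariates and a jittered phantom spec for one synthetic patient."""
    covariates = _draw_covariates(spec, rng)
    template = dict(spec.template or site_template(spec.site))
    center = np.asarray(template["target_center_mm"], dtype=float)
    center = center + rng.uniform(-3.0, 3.0, size=3)
    radius = float(template["target_radius_mm"] * rng.uniform(0.9, 1.1))
    phantom = PhantomSpec(
        compartments=template["compartments"],
        target_center_mm=tuple(center),
        target_radius_mm=radius,
        beam_axis=int(template.get("beam_axis", 1)),
        prescription_gy=covariates["prescription_gy"],
        n_fractions=covariates["n_fractions"],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return covariates, phantom


def _simulated_doses(
    phantom: PhantomSpec, sex: str, n_particles: int, seed: int
) -> dict[str, float]:
    """Blood D_90% and per-compartment DVH D_90 from the full simulator."""
    dose, masks, plan_meta = make_phantom(phantom)
    model = build_patient_model(
        dose,
        masks,
        default_physiology(sex),
        load_physiology_table(),
        load_coverage_table(),
    )
    schedule = build_schedule(plan_meta)
    params = CirculationParams(n_particles=n_particles, rng_seed=seed)
    distribution = score_course(model, params, schedule)
    metrics = compute_metrics(distribution, x_levels=(10.0, 90.0))
    row = {"d90_blood": metrics.d_x[90.0], "d10_blood": metrics.d_x[10.0]}
    for compartment in model.compartments:
        row[f"d90_{compartment.name}"] = compartment_dvh_metric(compartment, 90.0)
    return row


def _event_draw(
    hazard: float, censoring_rate: float, rng: np.random.Generator
) -> tuple[float, int]:
    event_time = rng.exponential(1.0 / hazard)
    if censoring_rate <= 0:
        return event_time, 1
    # With C ~ Exp(h*c/(1-c)) and T ~ Exp(h), P(C < T) = c exactly.
    censor_rate = hazard * censoring_rate / (1.0 - censoring_rate)
    censor_time = rng.exponential(1.0 / censor_rate)
    if event_time <= censor_time:
        return event_time, 1
    return censor_time, 0


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Generate a cohort table and return it with its ground truth.

    Returns ``(table, truth)`` where ``table`` has one row per patient
    (covariates, blood/compartment dose metrics, and per-endpoint
    ``time_<ep>``/``event_<ep>`` columns in days) and ``truth`` records the
    declared generative parameters.
    """
    root = np.random.SeedSequence(spec.seed)
    rows: list[dict[str, Any]] = []
    for index, child in enumerate(root.spawn(spec.n_patients)):
        rng = np.random.default_rng(child)
        covariates, phantom = sample_patient(spec, index, rng)
        row: dict[str, Any] = {"patient_id": f"p{index:04d}", **covariates}
        if spec.dose_mode == "simulate":
            row.update(
                _simulated_doses(
                    phantom,
                    covariates["sex"],
                    spec.n_particles,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
        else:
            draw = rng.normal(spec.dose_mean_gy, spec.dose_sd_gy)
            row["d90_blood"] = float(np.maximum(draw, 0.01))

        linear_predictor = sum(beta * float(row[name]) for name, beta in spec.betas.items())
        hazard = spec.baseline_hazard_per_day * np.exp(linear_predictor)
        for endpoint in spec.endpoints:
            time, event = _event_draw(hazard, spec.censoring_rate, rng)
            row[f"time_{endpoint.lower()}"] = time
            row[f"event_{endpoint.lower()}"] = event
        rows.append(row)

    table = pd.DataFrame(rows)
    truth = {
        "betas": dict(spec.betas),
        "baseline_hazard_per_day": spec.baseline_hazard_per_day,
        "censoring_rate": spec.censoring_rate,
        "site": spec.site,
        "dose_mode": spec.dose_mode,
        "seed": spec.seed,
    }
    return table, truth
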