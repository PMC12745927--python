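"""Patient anatomy represented as a set of blood compartments.

A patient is modelled as a 3D absorbed-dose grid plus a collection of
compartments (organs, vessel groups, generic tissues).  Each compartment
holds a fixed fraction of the total blood volume (``f_volume``) and
receives a fixed fraction of the cardiac output (``f_flow``); its spatial
extent is a binary label map congruent with the dose grid, from which a
sorted sample of whole-course voxel doses is extracted.  An automatically
constructed ``rest_of_body`` remainder compartment closes the volume- and
flow-fraction budgets so that both sum to exactly one over the patient.

Compartments only partially inside the imaged field of view carry a
``coverage`` fraction in (0, 1]; the out-of-view portion is assumed to lie
far from the irradiated target and to receive no dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "DoseGrid",
    "LabelMap",
    "PatientPhysiology",
    "CompartmentModel",
    "PatientModel",
    "REST_OF_BODY",
    "default_physiology",
    "exclude_cavity",
    "extract_voxel_doses",
    "build_patient_model",
]

REST_OF_BODY = "rest_of_body"

#: ICRP Report 89 reference total blood volume (L) and cardiac output (L/min).
ICRP89_REFERENCE = {
    "female": (3.9, 5.9),
    "male": (5.3, 6.5),
}


class ConfigurationError(ValueError):
    """Raised for invalid physiology/coverage configuration or unknown keys."""


@dataclass(frozen=True)
class DoseGrid:
    """A 3D absorbed-dose distribution for the whole treatment course.

    Parameters
    ----------
    values
        3D array of absorbed dose in Gy, axis order (z, y, x).
    spacing
        Voxel edge lengths in mm, one per axis.
    origin
        Physical coordinates (mm) of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"dose grid must be 3D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("dose grid contains non-finite values")
        if values.min() < 0:
            raise ValueError("dose grid contains negative dose")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_l(self) -> float:
        return self.voxel_volume_mm3 * 1e-6


@dataclass(frozen=True)
class LabelMap:
    """A named binary mask congruent with a :class:`DoseGrid`."""

    mask: np.ndarray
    name: str

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"label map must be 3D, got ndim={mask.ndim}")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PatientPhysiology:
    """Whole-body circulatory reference values."""

    sex: str
    total_blood_volume_l: float
    cardiac_output_l_min: float

    def __post_init__(self) -> None:
        if self.total_blood_volume_l <= 0 or self.cardiac_output_l_min <= 0:
            raise ValueError("blood volume and cardiac output must be positive")


def default_physiology(
    sex: str, overrides: Mapping[str, tuple[float, float]] | None = None
) -> PatientPhysiology:
    """Return reference physiology for a patient of the given sex.

    Defaults are the ICRP-89 reference values: total blood volume 3.9 L and
    cardiac output 5.9 L/min for female patients, 5.3 L and 6.5 L/min for
    male patients.  ``overrides`` maps a sex token to a
    ``(total_blood_volume_l, cardiac_output_l_min)`` pair and is returned
    verbatim when it contains the requested sex.
    """
    table = dict(ICRP89_REFERENCE)
    if overrides:
        table.update(overrides)
    try:
        volume, output = table[sex]
    except KeyError:
        raise ConfigurationError(
            f"unknown sex {sex!r}; expected one of {sorted(table)}"
        ) from None
    return PatientPhysiology(sex=sex, total_blood_volume_l=volume, cardiac_output_l_min=output)


def exclude_cavity(organ: LabelMap, cavity: LabelMap) -> LabelMap:
    """Remove an irradiated surgical cavity from an organ label map.

    Returns ``organ AND NOT cavity``.  If the cavity does not intersect the
    organ, the organ is returned unchanged; an empty result (cavity covering
    the whole organ) is an error because the compartment would have no
    voxels left to sample doses from.
    """
    if organ.mask.shape != cavity.mask.shape:
        raise ValueError(
            f"shape mismatch: organ {organ.mask.shape} vs cavity {cavity.mask.shape}"
        )
    if not np.any(organ.mask & cavity.mask):
        return organ
    result = organ.mask & ~cavity.mask
    if not result.any():
        raise ValueError(f"cavity removes every voxel of compartment {organ.name!r}")
    marker = "[cavity-excluded]"
    name = organ.name if organ.name.endswith(marker) else organ.name + marker
    return LabelMap(mask=result, name=name)


def extract_voxel_doses(dose: DoseGrid, mask: LabelMap | np.ndarray) -> np.ndarray:
    """Sorted (ascending) sample of whole-course voxel doses under a mask."""
    arr = mask.mask if isinstance(mask, LabelMap) else np.asarray(mask, dtype=bool)
    if arr.shape != dose.shape:
        raise ValueError(f"mask shape {arr.shape} does not match dose grid {dose.shape}")
    if not arr.any():
        raise ValueError("cannot extract voxel doses from an empty mask")
    return np.sort(dose.values[arr])


@dataclass(frozen=True)
class CompartmentModel:
    """One blood compartment: physiology fractions, geometry, dose content.

    ``voxel_doses`` is the ascending whole-course dose sample (Gy) inside
    the (cavity-excluded) mask; it is the source for compartment DVH
    metrics and for dose sampling during particle transport.
    """

    name: str
    f_volume: float
    f_flow: float
    voxel_doses: np.ndarray
    coverage: float = 1.0
    label_map: LabelMap | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.f_volume <= 1.0):
            raise ValueError(f"{self.name}: f_volume must be in (0, 1], got {self.f_volume}")
        if not (0.0 < self.f_flow <= 1.0):
            raise ValueError(f"{self.name}: f_flow must be in (0, 1], got {self.f_flow}")
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError(f"{self.name}: coverage must be in (0, 1], got {self.coverage}")
        doses = np.sort(np.asarray(self.voxel_doses, dtype=float).ravel())
        if doses.size == 0:
            raise ValueError(f"{self.name}: voxel_doses must be non-empty")
        if doses[0] < 0 or not np.all(np.isfinite(doses)):
            raise ValueError(f"{self.name}: voxel_doses must be finite and non-negative")
        object.__setattr__(self, "voxel_doses", doses)

    @property
    def mean_voxel_dose(self) -> float:
        return float(self.voxel_doses.mean())


@dataclass(frozen=True)
class PatientModel:
    """Assembled per-patient input to the circulation/scoring simulation."""

    physiology: PatientPhysiology
    compartments: tuple[CompartmentModel, ...]
    dose_grid: DoseGrid | None = None

    def __post_init__(self) -> None:
        compartments = tuple(self.compartments)
        if not compartments:
            raise ValueError("patient model needs at least one compartment")
        names = [c.name for c in compartments]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate compartment names: {names}")
        total = sum(c.f_volume for c in compartments)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartment f_volume fractions sum to {total}, expected 1")
        object.__setattr__(self, "compartments", compartments)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments)

    @property
    def f_volumes(self) -> np.ndarray:
        return np.array([c.f_volume for c in self.compartments])

    @property
    def f_flows(self) -> np.ndarray:
        return np.array([c.f_flow for c in self.compartments])

    def __getitem__(self, name: str) -> CompartmentModel:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)


def build_patient_model(
    dose: DoseGrid,
    masks: Mapping[str, LabelMap] | Sequence[LabelMap],
    physiology: PatientPhysiology,
    physiology_table: Mapping[str, Mapping[str, float]],
    coverage_table: Mapping[str, float] | None = None,
    body_mask: LabelMap | None = None,
) -> PatientModel:
    """Assemble a :class:`PatientModel` from dose, masks, and config tables.

    Each mask must correspond to an entry in ``physiology_table`` supplying
    its ``f_volume`` and ``f_flow``.  A ``rest_of_body`` remainder
    compartment is appended automatically; it takes the unassigned volume
    and flow fractions and samples its voxel doses from the body (by
    default the whole grid) minus the union of the explicit masks, so the
    model's volume fractions always close to exactly one.
    """
    coverage_table = coverage_table or {}
    if not isinstance(masks, Mapping):
        masks = {m.name: m for m in masks}

    compartments: list[CompartmentModel] = []
    union = np.zeros(dose.shape, dtype=bool)
    sum_fv = 0.0
    sum_ff = 0.0
    for name, label in masks.items():
        if name not in physiology_table:
            raise ConfigurationError(f"compartment {name!r} missing from physiology table")
        entry = physiology_table[name]
        f_volume = float(entry["f_volume"])
        f_flow = float(entry["f_flow"])
        coverage = float(coverage_table.get(name, 1.0))
        voxel_doses = extract_voxel_doses(dose, label)
        compartments.append(
            CompartmentModel(
                name=name,
                f_volume=f_volume,
                f_flow=f_flow,
                coverage=coverage,
                voxel_doses=voxel_doses,
                label_map=label,
            )
        )
        union |= label.mask
        sum_fv += f_volume
        sum_ff += f_flow

    if sum_fv >= 1.0:
        raise ConfigurationError(
            f"explicit compartments claim {sum_fv:.3f} of the blood volume; "
            "the rest-of-body remainder requires a strictly positive share"
        )
    if sum_ff >= 1.0:
        raise ConfigurationError(
            f"explicit compartments claim {sum_ff:.3f} of the cardiac output; "
            "the rest-of-body remainder requires a strictly positive share"
        )

    body = body_mask.mask if body_mask is not None else np.ones(dose.shape, dtype=bool)
    remainder_mask = body & ~union
    if not remainder_mask.any():
        raise ConfigurationError(
            "rest-of-body mask is empty: explicit compartments cover the whole body"
        )
    remainder = CompartmentModel(
        name=REST_OF_BODY,
        f_volume=1.0 - sum_fv,
        f_flow=1.0 - sum_ff,
        coverage=float(coverage_table.get(REST_OF_BODY, 1.0)),
        voxel_doses=extract_voxel_doses(dose, remainder_mask),
        label_map=LabelMap(mask=remainder_mask, name=REST_OF_BODY),
    )
    compartments.append(remainder)
    # Close the volume budget exactly (floating sums can drift by ~1e-16).
    total = sum(c.f_volume for c in compartments)
    if total != 1.0:
        fixed = remainder.f_volume + (1.0 - total)
        compartments[-1] = CompartmentModel(
            name=remainder.name,
            f_volume=fixed,
            f_flow=remainder.f_flow,
            coverage=remainder.coverage,
            voxel_doses=remainder.voxel_doses,
            label_map=remainder.label_map,
        )
    return PatientModel(physiology=physiology, compartments=tuple(compartments), dose_grid=dose)
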