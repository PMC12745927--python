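"""Blood-dose summary metrics and static comparator dose models.

Dynamic metrics reduce the per-particle dose distribution to D_mean (the
arithmetic mean over particles), D_X% (the minimum dose among the top X%
highest-dose particles) and V_YGy (the percentage of particles receiving
at least Y Gy).  The same top-X% statistic applied to a compartment's
voxel-dose sample is the standard DVH D_X.

Three static comparators are provided: the body dose (mean dose over the
body mask, with the integral Gy·L form reported alongside), the mean dose
over the union of all compartment label maps, and the effective dose to
immune cells (EDIC) — a weighted combination of mean lung, heart, liver
and body doses that is only applicable when all three organs are imaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .anatomy import CompartmentModel, DoseGrid, LabelMap

__all__ = [
    "BloodDoseMetrics",
    "StaticBodyDose",
    "compute_metrics",
    "dose_at_top_fraction",
    "static_body_dose",
    "static_hedos_dose",
    "edic",
    "compartment_dvh_metric",
    "DEFAULT_X_LEVELS",
    "DEFAULT_Y_LEVELS",
    "DEFAULT_EDIC_COEFFICIENTS",
]

DEFAULT_X_LEVELS = (10.0, 90.0)
DEFAULT_Y_LEVELS = (1.0, 5.0, 10.0)

#: EDIC weights: mean organ doses enter with fixed coefficients while the
#: mean body dose coefficient grows with the number of fractions as
#: body_base + body_slope * (n_fractions / 45).  Values transcribed from the
#: published immune-cell dose model for fractionated photon therapy; see
#: data/edic.yaml and docs/methods.md.
DEFAULT_EDIC_COEFFICIENTS = {
    "lung": 0.12,
    "heart": 0.08,
    "liver": 0.15,
    "body_base": 0.45,
    "body_slope": 0.2975,
}


@dataclass(frozen=True)
class BloodDoseMetrics:
    """Summary of a particle-dose distribution."""

    d_mean: float
    d_x: dict[float, float]
    v_y: dict[float, float]

    def as_row(self, prefix: str = "") -> dict[str, float]:
        row = {f"{prefix}d_mean": self.d_mean}
        for x, value in self.d_x.items():
            row[f"{prefix}d_{x:g}pct"] = value
        for y, value in self.v_y.items():
            row[f"{prefix}v_{y:g}gy"] = value
        return row


class StaticBodyDose(NamedTuple):
    mean_gy: float
    integral_gy_l: float


def dose_at_top_fraction(sorted_doses: np.ndarray, x: float) -> float:
    """Minimum dose among the top X% highest entries of an ascending sample.

    The top group contains ceil(X% · N) entries; ties at the threshold dose
    all belong to the top group by construction (the statistic is the dose
    value at the group boundary).  D_100% is the sample minimum.
    """
    if not (0.0 < x <= 100.0):
        raise ValueError(f"X must be in (0, 100], got {x}")
    n = sorted_doses.size
    n_top = math.ceil(x / 100.0 * n)
    return float(sorted_doses[n - n_top])


def compute_metrics(
    distribution,
    x_levels: Sequence[float] = DEFAULT_X_LEVELS,
    y_levels: Sequence[float] = DEFAULT_Y_LEVELS,
) -> BloodDoseMetrics:
    """Compute D_mean, D_X% and V_YGy for a particle-dose distribution.

    ``distribution`` may be a :class:`~hemodose.delivery.ParticleDoseDistribution`
    or a bare dose vector.
    """
    doses = np.asarray(getattr(distribution, "doses", distribution), dtype=float).ravel()
    if doses.size == 0:
        raise ValueError("dose vector must be non-empty")
    for y in y_levels:
        if y < 0:
            raise ValueError(f"V_Y level must be non-negative, got {y}")
    ordered = np.sort(doses)
    d_x = {float(x): dose_at_top_fraction(ordered, x) for x in x_levels}
    v_y = {float(y): float(100.0 * np.mean(doses >= y)) for y in y_levels}
    return BloodDoseMetrics(d_mean=float(doses.mean()), d_x=d_x, v_y=v_y)


def static_body_dose(dose: DoseGrid, body: LabelMap) -> StaticBodyDose:
    """Body-dose static comparator.

    Returns both conventions: the mean dose over the body mask (Gy; used
    as the Cox covariate so all dose covariates share Gy units) and the
    integral form, mean × body volume (Gy·L).
    """
    mask = body.mask
    if mask.shape != dose.shape:
        raise ValueError("body mask shape does not match dose grid")
    if not mask.any():
        raise ValueError("body mask is empty")
    mean = float(dose.values[mask].mean())
    volume_l = mask.sum() * dose.voxel_volume_l
    return StaticBodyDose(mean_gy=mean, integral_gy_l=mean * volume_l)


def static_hedos_dose(dose: DoseGrid, compartment_masks: Iterable[LabelMap]) -> float:
    """Mean dose over the voxel-wise union of all compartment label maps."""
    union = np.zeros(dose.shape, dtype=bool)
    seen = False
    for label in compartment_masks:
        if label.mask.shape != dose.shape:
            raise ValueError(f"mask {label.name!r} shape does not match dose grid")
        union |= label.mask
        seen = True
    if not seen:
        raise ValueError("at least one compartment mask is required")
    if not union.any():
        raise ValueError("union of compartment masks is empty")
    return float(dose.values[union].mean())


def edic(
    mean_lung_dose: float | None,
    mean_heart_dose: float | None,
    mean_liver_dose: float | None,
    mean_body_dose: float,
    n_fractions: int,
    coefficients: Mapping[str, float] | None = None,
) -> float | None:
    """Effective dose to immune cells (Gy), or None when not applicable.

    Requires mean doses for the lungs, heart and liver: if any of them is
    missing (organ outside the imaged field of view) the model cannot be
    applied and ``None`` is returned — explicitly not zero.
    """
    if mean_lung_dose is None or mean_heart_dose is None or mean_liver_dose is None:
        return None
    for name, value in (
        ("lung", mean_lung_dose),
        ("heart", mean_heart_dose),
        ("liver", mean_liver_dose),
        ("body", mean_body_dose),
    ):
        if value < 0:
            raise ValueError(f"mean {name} dose must be non-negative, got {value}")
    c = dict(DEFAULT_EDIC_COEFFICIENTS)
    if coefficients:
        c.update(coefficients)
    body_coefficient = c["body_base"] + c["body_slope"] * (n_fractions / 45.0)
    return float(
        c["lung"] * mean_lung_dose
        + c["heart"] * mean_heart_dose
        + c["liver"] * mean_liver_dose
        + body_coefficient * mean_body_dose
    )


def compartment_dvh_metric(compartment: CompartmentModel | np.ndarray, x: float) -> float:
    """DVH D_X of a compartment: minimum dose among its hottest X% of voxels."""
    if isinstance(compartment, CompartmentModel):
        doses = compartment.voxel_doses
    else:
        doses = np.sort(np.asarray(compartment, dtype=float).ravel())
    if doses.size == 0:
        raise ValueError("voxel-dose sample must be non-empty")
    return dose_at_top_fraction(doses, x)
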