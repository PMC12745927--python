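"""File I/O: NIfTI grids and masks, plan JSON, config tables, dose vectors.

Grids are stored as NIfTI with a diagonal affine built from the voxel
spacing; arrays use (z, y, x) axis order internally.  Resampling of masks
onto the dose grid is nearest-neighbour and assumes axis-aligned grids
sharing an origin (the synthetic phantoms always satisfy this).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import yaml

from .anatomy import DoseGrid, LabelMap

__all__ = [
    "save_dose",
    "load_dose",
    "save_mask",
    "load_mask",
    "resample_mask_nn",
    "save_plan",
    "load_plan",
    "save_particle_doses",
    "load_particle_doses",
    "load_physiology_table",
    "load_coverage_table",
    "load_edic_coefficients",
]


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    return affine


def save_dose(grid: DoseGrid, path: str | Path) -> None:
    image = nib.Nifti1Image(grid.values.astype(np.float32), _affine(grid.spacing, grid.origin))
    nib.save(image, str(path))


def load_dose(path: str | Path) -> DoseGrid:
    image = nib.load(str(path))
    spacing = tuple(float(z) for z in image.header.get_zooms()[:3])
    origin = tuple(float(v) for v in np.asarray(image.affine)[:3, 3])
    return DoseGrid(values=np.asarray(image.dataobj, dtype=float), spacing=spacing, origin=origin)


def save_mask(label: LabelMap, spacing: tuple[float, float, float], path: str | Path) -> None:
    image = nib.Nifti1Image(label.mask.astype(np.uint8), _affine(spacing, (0.0, 0.0, 0.0)))
    nib.save(image, str(path))


def load_mask(path: str | Path, name: str | None = None, grid: DoseGrid | None = None) -> LabelMap:
    """Load a binary mask; optionally resample it onto ``grid``."""
    image = nib.load(str(path))
    mask = np.asarray(image.dataobj) > 0.5
    if name is None:
        name = Path(path).name.split(".")[0]
    if grid is not None and mask.shape != grid.shape:
        spacing = tuple(float(z) for z in image.header.get_zooms()[:3])
        mask = resample_mask_nn(mask, spacing, grid.shape, grid.spacing)
    return LabelMap(mask=mask, name=name)


def resample_mask_nn(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    target_shape: tuple[int, int, int],
    target_spacing: tuple[float, float, float],
) -> np.ndarray:
    """Nearest-neighbour resample of an axis-aligned mask onto a target grid."""
    indices = []
    for axis in range(3):
        centers = np.arange(target_shape[axis]) * target_spacing[axis]
        source = np.rint(centers / spacing[axis]).astype(int)
        indices.append(np.clip(source, 0, mask.shape[axis] - 1))
    return mask[np.ix_(*indices)]


def save_plan(plan_meta: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(plan_meta), indent=2))


def load_plan(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def save_particle_doses(distribution, path: str | Path) -> None:
    np.savez_compressed(str(path), doses=distribution.doses, meta=json.dumps(distribution.meta))


def load_particle_doses(path: str | Path):
    from .delivery import ParticleDoseDistribution

    archive = np.load(str(path), allow_pickle=False)
    meta = json.loads(str(archive["meta"])) if "meta" in archive else {}
    return ParticleDoseDistribution(doses=archive["doses"], meta=meta)


def _packaged(name: str) -> dict:
    text = resources.files("hemodose.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def load_physiology_table(path: str | Path | None = None) -> dict[str, dict[str, float]]:
    """Compartment f_volume/f_flow table (shipped defaults unless ``path``)."""
    data = yaml.safe_load(Path(path).read_text()) if path else _packaged("physiology.yaml")
    return data["compartments"]


def load_coverage_table(path: str | Path | None = None) -> dict[str, float]:
    data = yaml.safe_load(Path(path).read_text()) if path else _packaged("coverage.yaml")
    return data.get("coverage", {})


def load_edic_coefficients(path: str | Path | None = None) -> dict[str, float]:
    data = yaml.safe_load(Path(path).read_text()) if path else _packaged("edic.yaml")
    return data["coefficients"]
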