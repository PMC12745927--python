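import numpy as np
import pytest

from hemodose import (
    CompartmentModel,
    DoseGrid,
    LabelMap,
    PatientModel,
    default_physiology,
)


@pytest.fixture
def male_physiology():
    return default_physiology("male")


@pytest.fixture
def two_compartment_model(male_physiology):
    """f_volume (0.7, 0.3) pair used by the steady-state occupancy checks."""
    compartments = (
        CompartmentModel(name="a", f_volume=0.7, f_flow=0.5, voxel_doses=[0.0]),
        CompartmentModel(name="b", f_volume=0.3, f_flow=0.5, voxel_doses=[0.0]),
    )
    return PatientModel(physiology=male_physiology, compartments=compartments)


def make_uniform_model(physiology, dose_gy, f_volumes=(0.3, 0.7), coverage=(1.0, 1.0)):
    """Every compartment's voxel-dose sample is the constant ``dose_gy``."""
    compartments = tuple(
        CompartmentModel(
            name=f"c{i}",
            f_volume=fv,
            f_flow=fv,
            coverage=cov,
            voxel_doses=[dose_gy],
        )
        for i, (fv, cov) in enumerate(zip(f_volumes, coverage))
    )
    return PatientModel(physiology=physiology, compartments=compartments)


@pytest.fixture
def ramp_grid():
    """16^3 grid with dose increasing linearly along the z axis."""
    n = 16
    values = np.broadcast_to(np.arange(n, dtype=float)[:, None, None], (n, n, n)).copy()
    return DoseGrid(values=values, spacing=(2.0, 2.0, 2.0))


@pytest.fixture
def half_space_mask(ramp_grid):
    mask = np.zeros(ramp_grid.shape, dtype=bool)
    mask[: ramp_grid.shape[0] // 2] = True
    return LabelMap(mask=mask, name="half")
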