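import numpy as np
import pytest

from arcadapt import (
    PhantomConfig,
    RangeEnergyModel,
    make_initial_plan,
    make_phantom,
)


@pytest.fixture(scope="session")
def small_phantom():
    """36^3 phantom at 3 mm spacing: body, single target, serial OAR."""
    cfg = PhantomConfig(
        shape=(36, 36, 36), spacing=(3.0, 3.0, 3.0),
        target_high_radius_mm=13.0, target_low_semiaxes_mm=None,
        oar_offset_mm=24.0, oar_halflength_mm=40.0,
        center_jitter_mm=0.0, seed=7,
    )
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def water_grid():
    """Uniform water cube, 60^3 voxels at 2 mm, centred at the origin."""
    from arcadapt import VoxelGrid

    shape = (60, 60, 60)
    spacing = np.array([2.0, 2.0, 2.0])
    origin = -(np.array(shape) - 1) / 2.0 * spacing
    return VoxelGrid(values=np.ones(shape, dtype=np.float32), spacing=spacing, origin=origin)


@pytest.fixture(scope="session")
def model():
    return RangeEnergyModel()


@pytest.fixture(scope="session")
def small_plan(small_phantom):
    grid, structures = small_phantom
    return make_initial_plan(
        structures, grid, n_control_points=12, lateral_spacing_mm=8.0,
        margin_mm=3.0, max_switch_ups=3,
        prescriptions={"target_high": 70.0},
    )
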