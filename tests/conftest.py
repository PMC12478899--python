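import warnings

import numpy as np
import pytest

from sensillum3d.geometry import VoxelGeometry
from sensillum3d.synthgen import ConeSpec, PhantomStackSpec, make_phantom_stack

# statsmodels emits benign convergence chatter on tiny synthetic fits
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture
def demo_geometry():
    """Desk-scale voxel calibration: 200 nm XY, 150 nm Z."""
    return VoxelGeometry(pixel_x=200.0, pixel_y=200.0, slice_z=150.0)


@pytest.fixture
def chamber1_cone():
    """Chamber-1-like elongated cone: reported base width and taper."""
    return ConeSpec(base_width=3.36, height=3.36 / 0.472, taper_slope=-0.472,
                    points_n=2500)


@pytest.fixture
def squat_cone():
    """Chamber-2-like squat cone: height comparable to width."""
    return ConeSpec(base_width=3.3, height=3.3 / 0.959, taper_slope=-0.959,
                    points_n=1500)


@pytest.fixture
def phantom_pair(demo_geometry):
    """Small noise-free phantom with one interior cone, plus its labels."""
    cone = ConeSpec(base_width=3.0, height=5.0, taper_slope=-0.6,
                    apex_offset=(6.4, 6.4, 0.3), points_n=100)
    spec = PhantomStackSpec(sections_n=40, section_shape=(64, 64),
                            geometry=demo_geometry, cones=(cone,), noise_sd=0.0,
                            seed=0)
    return make_phantom_stack(spec), spec


@pytest.fixture
def training_phantom(demo_geometry):
    """Four-cone noisy phantom sized for a minute-scale U-Net run."""
    rng = np.random.default_rng(5)
    cones = tuple(
        ConeSpec(base_width=3.3, height=6.5, taper_slope=-0.45,
                 axis_direction=(0.05 * rng.normal(), 0.05 * rng.normal(), 1.0),
                 apex_offset=(3.2 + 6.0 * (i % 2), 3.2 + 6.0 * (i // 2), 0.3),
                 points_n=100)
        for i in range(4))
    spec = PhantomStackSpec(sections_n=48, section_shape=(64, 64),
                            geometry=demo_geometry, cones=cones, noise_sd=12.0,
                            seed=7)
    return make_phantom_stack(spec)
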