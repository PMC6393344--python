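import numpy as np
import pytest

from fibrekin.synthetic import SOLID, FiberSpec, VoxelVolume, generate_fiber


@pytest.fixture
def solid_bar():
    """Homogeneous 12x4x4 solid bar, 1 um voxels."""
    data = np.full((12, 4, 4), SOLID, dtype=np.uint8)
    return VoxelVolume(data, 1.0)


@pytest.fixture
def tube_volume():
    """Fiber with a single tubular lumen spanning the full length."""
    spec = FiberSpec(
        diameter=20, length=30, shape_factor=1.5,
        lumen=True, lumen_area_fraction=0.10, voxel_size=1.0,
    )
    return generate_fiber(spec, seed=1)


@pytest.fixture
def plain_cylinder():
    """Lumen-free circular fiber."""
    spec = FiberSpec(diameter=20, length=30, lumen=False, voxel_size=1.0)
    return generate_fiber(spec, seed=1)
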