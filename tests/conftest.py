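import numpy as np
import pytest

from edgesync.trials import VoxelSpace


def full_space(dims, voxel_size_mm=(3.0, 3.0, 3.0)) -> VoxelSpace:
    return VoxelSpace(mask=np.ones(dims, dtype=bool), voxel_size_mm=voxel_size_mm)


@pytest.fixture
def space_3x3x3():
    return full_space((3, 3, 3))


@pytest.fixture
def space_8():
    return full_space((8, 8, 8))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
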