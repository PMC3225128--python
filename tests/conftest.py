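import numpy as np
import pytest

from segbench3d.stack_io import IntensityStack, LabelStack, VoxelCalibration


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def calibration():
    return VoxelCalibration(0.5, 0.5, 1.0)


def make_stack(voxels, bit_depth=8, calibration=None):
    return IntensityStack(
        voxels=np.asarray(voxels),
        bit_depth=bit_depth,
        calibration=calibration or VoxelCalibration(),
    )


def make_labels(labels, calibration=None):
    return LabelStack(labels=np.asarray(labels), calibration=calibration or VoxelCalibration())


@pytest.fixture
def random_stack(rng):
    """A small noisy 8-bit stack."""
    return make_stack(rng.integers(0, 256, size=(4, 16, 16)).astype(np.uint8))
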