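import numpy as np
import pytest

from motionssl.encoders import (IMUEncoderConfig, ProjectorConfig,
                                SkeletonEncoderConfig)
from motionssl.synthetic import GeneratorConfig, generate_dataset, split_dataset

# Narrow architectures for fast unit tests; the acceptance suite uses the
# package's desk-scale preset instead.
TINY_IMU = IMUEncoderConfig(conv_channels=(4, 8), model_dim=8)
TINY_SKELETON = SkeletonEncoderConfig(conv_channels=(4, 4, 4, 8, 8, 8), hidden_dim=8)
TINY_PROJECTOR = ProjectorConfig(layer_dims=(8, 8))


@pytest.fixture(scope="session")
def tiny_config():
    return GeneratorConfig(num_classes=3, samples_per_class=16, num_subjects=4,
                           frames=16, joints=4, coord_dim=2, imu_channels=6,
                           noise_sd=0.05, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return split_dataset(tiny_dataset)


def numerical_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
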