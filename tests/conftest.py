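import numpy as np
import pytest

from homopoint.model import HomologousPointNet, ModelConfig
from homopoint.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def phantom128():
    """One medium phantom with the scaled study's deformation magnitude."""
    return generate_phantom(11, PhantomParams(size=128, deformation_px=12, n_gt_points=24))


@pytest.fixture(scope="session")
def phantom128_rigid():
    return generate_phantom(11, PhantomParams(size=128, deformation_px=0, n_gt_points=24))


@pytest.fixture(scope="session")
def tiny_config():
    """Small config used for equation-oracle tests."""
    return ModelConfig(image_size=64, patch_size=8, embed_dim=16, n_blocks=2, n_heads=2, L=4)


@pytest.fixture(scope="session")
def tiny_net(tiny_config):
    return HomologousPointNet(tiny_config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
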