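import numpy as np
import pytest

from tomoinpaint import GrayImage, ModelConfig, PhantomParams, generate_phantom
from tomoinpaint.model import InpaintModel


@pytest.fixture(scope="session")
def small_phantom():
    """A 96x96 phantom slice plus tissue mask (fits the 64-px field of view)."""
    params = PhantomParams(height=96, width=96, texture_sigma=4.0, n_vessels=2,
                           edge_margin=0)
    rng = np.random.default_rng(123)
    image, mask = generate_phantom(params, rng)
    return image, mask


@pytest.fixture(scope="session")
def tiny_model():
    """Randomly initialized desk-scale model (fov 64, width 8)."""
    return InpaintModel(ModelConfig.tiny(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def flat_image(h=96, w=96, value=0.5):
    """Uniform all-tissue image."""
    return GrayImage(np.full((h, w), value))
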