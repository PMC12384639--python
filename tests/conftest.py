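import numpy as np
import pytest

from cmrdiff.nn.unet import UNetSpec, build_unet
from cmrdiff.phantom import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


TINY_SPEC = UNetSpec(image_size=16, level_channels=(8, 16),
                     down_kinds=("plain", "attn"), up_kinds=("attn", "plain"),
                     heads=2, norm_groups=4, attn_max_resolution=16)


@pytest.fixture(scope="session")
def tiny_spec():
    return TINY_SPEC


@pytest.fixture(scope="session")
def tiny_model():
    return build_unet(TINY_SPEC, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def phantom_cohort():
    """200 default-config phantoms shared across tests (images, masks)."""
    cfg = PhantomConfig()
    images, masks, manifest = generate_dataset(200, cfg, seed=99)
    return images, masks, manifest


@pytest.fixture(scope="session")
def toy_phantoms16():
    """Small 16x16 zoomed phantoms for quick training runs."""
    cfg = PhantomConfig.for_size(16, zoom=2.5)
    images, masks, _ = generate_dataset(96, cfg, seed=5)
    return images, masks
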