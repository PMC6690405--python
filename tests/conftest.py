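import numpy as np
import pytest

from glandseg import synth


@pytest.fixture(scope="session")
def small_params():
    """A small but fully featured synthetic tile: 4 glands, lumina, white blob."""
    return synth.SynthParams(tile_size=160, n_glands=4,
                             gland_radius_range=(14, 24), seed=5)


@pytest.fixture(scope="session")
def small_tile(small_params):
    tile, inst = synth.generate_tissue(small_params)
    return tile, inst


@pytest.fixture(scope="session")
def tiny_model_cfg():
    from glandseg.model import ModelConfig
    return ModelConfig(block_layers=(2, 2, 2, 2), growth_rate=8, input_size=64,
                       decoder_channels=(16, 16, 8, 8, 8), seed=0)


def random_binary_mask(rng: np.random.Generator, shape=(32, 32), p=0.3):
    """Blob-ish random mask: thresholded smoothed noise, possibly empty."""
    from scipy import ndimage
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    return noise > np.quantile(noise, 1 - p)
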