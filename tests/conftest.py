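import numpy as np
import pytest

from mptexture.imaging_io import Channel, FieldOfView
from mptexture.texture_features import TextureConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return TextureConfig()


@pytest.fixture
def small_config():
    # small FoVs for fast unit tests: distances that fit a 32x48 grid
    return TextureConfig(distances_um=(2.0, 5.0), fov_rows=32, fov_cols=48)


def make_fov(pixels, channel=Channel.CARS, sample_id="s1", grid_row=0, grid_col=0,
             pixel_size_um=1.0):
    return FieldOfView(pixels=np.asarray(pixels, dtype=float), grid_row=grid_row,
                       grid_col=grid_col, sample_id=sample_id, channel=channel,
                       pixel_size_um=pixel_size_um)


@pytest.fixture
def fov_factory():
    return make_fov
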