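import numpy as np
import pytest

from exmkit import synthgen


@pytest.fixture
def textured_image():
    """A blob field with enough features for keypoint registration."""
    return synthgen.blob_template((200, 200), n_blobs=120, seed=6)


@pytest.fixture
def dense_texture():
    """A dense fine-grained blob field for block-matching tests."""
    return synthgen.blob_template((256, 256), n_blobs=2500,
                                  sigma_range=(0.8, 1.5), seed=5)


def single_emitter_movie(seed, frames=100, amplitude=2000.0, dwell=5.0,
                         poisson=True, shape=(33, 33)):
    cx = (shape[1] - 1) / 2.0
    cy = (shape[0] - 1) / 2.0
    em = synthgen.EmitterField([[cx, cy]], [amplitude], 0.5, dwell, dwell,
                               seed=seed)
    return synthgen.gen_blinking_movie(em, psf_fwhm_nm=300.0, pixel_nm=100.0,
                                       shape=shape, frames=frames,
                                       poisson=poisson, seed=seed)
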