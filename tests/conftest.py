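import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter

import lvtrack as lt


@pytest.fixture(scope="session")
def window():
    return lt.gaussian_window(21, 5.0)


@pytest.fixture(scope="session")
def table1_scene():
    """The reference 4-frame scene, generated once per session (seed 0)."""
    return lt.table1_fixture(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_textured_pair(shift=(0.0, 0.0), shape=(96, 128), seed=0, sigma=2.0):
    """A smooth textured frame and its exact subpixel translate.

    The second frame is produced by Fourier shifting, so brightness
    constancy holds exactly (up to wrap-around far from the interior).
    """
    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.standard_normal(shape), sigma) * 60.0 + 120.0
    shifted = np.fft.ifft2(
        fourier_shift(np.fft.fft2(base), (shift[1], shift[0]))
    ).real
    return base, shifted


@pytest.fixture()
def textured_pair():
    return make_textured_pair(shift=(0.5, 0.0), seed=3)
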