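import numpy as np
import pytest

from anthochrome.spectra import Spectrum


@pytest.fixture
def gaussian_spectrum():
    """Single Gaussian band centred inside the violet-contribution window."""

    def _make(center=550.0, sigma=30.0, height=1.0, step=1.0):
        wl = np.arange(400.0, 700.0 + step / 2, step)
        a = height * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        return Spectrum(wl, a)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
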