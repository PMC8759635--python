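import numpy as np
import pytest
from scipy import ndimage

from flowseg import FlowParams, ImageFrame


@pytest.fixture(scope="session")
def smooth_texture():
    """Seeded 128x128 smooth random texture in [0.1, 0.9]."""
    rng = np.random.default_rng(42)
    base = ndimage.gaussian_filter(rng.standard_normal((128, 128)), 3.0)
    base = (base - base.min()) / (base.max() - base.min())
    return 0.1 + 0.8 * base


@pytest.fixture
def flow_params():
    return FlowParams()


def circular_shift_pair(texture: np.ndarray, dr: int, dc: int):
    """Frame pair where frame 1 is frame 0 circularly shifted by (dr, dc)."""
    f0 = ImageFrame(texture, index=0)
    f1 = ImageFrame(np.roll(texture, (dr, dc), axis=(0, 1)), index=1)
    return f0, f1


def fourier_shift_pair(texture: np.ndarray, dr: float, dc: float):
    """Bandlimited subpixel shift via Fourier phase ramp."""
    F = np.fft.fft2(texture)
    ky = np.fft.fftfreq(texture.shape[0])[:, None]
    kx = np.fft.fftfreq(texture.shape[1])[None, :]
    shifted = np.real(np.fft.ifft2(F * np.exp(-2j * np.pi * (ky * dr + kx * dc))))
    f0 = ImageFrame(texture, index=0)
    f1 = ImageFrame(np.clip(shifted, 0.0, 1.0), index=1)
    return f0, f1


INTERIOR = (slice(16, -16), slice(16, -16))
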