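import numpy as np
import pytest

from hftmspc.stimulus_model import build_exp1_schedule


@pytest.fixture(scope="session")
def smooth_image():
    """A smooth, structured 64x64 test image with intensities in [0, 1]."""
    rng = np.random.default_rng(42)
    x = rng.random((64, 64))
    # low-pass in Fourier space so the image has contour-like structure
    X = np.fft.fft2(x)
    fy = np.fft.fftfreq(64)[:, None]
    fx = np.fft.fftfreq(64)[None, :]
    X *= np.exp(-((fx**2 + fy**2) / (2 * 0.08**2)))
    img = np.fft.ifft2(X).real
    img -= img.min()
    img /= img.max()
    return img


@pytest.fixture(scope="session")
def exp1_schedule():
    """A short expectation-style trial: 1.2 Hz SWIFT, 15 Hz SSVEP, 30 s."""
    return build_exp1_schedule("FHHFFH", task="PV", n_cycles=36, violation_index=17)
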