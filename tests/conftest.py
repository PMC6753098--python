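import numpy as np
import pytest
from hypothesis import settings

from batlipid import FatSpectrum, build_echo_schedule

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    """Default 18-echo, 3x6-interleaved schedule."""
    return build_echo_schedule()


@pytest.fixture(scope="session")
def spectrum():
    return FatSpectrum.seven_peak_3t()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def textured_volume():
    """Smooth, feature-rich intensity volume inside an elliptical body."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(7)
    shape = (64, 64, 15)
    tex = gaussian_filter(rng.standard_normal(shape), (2.5, 2.5, 1.0))
    tex = (tex - tex.min()) / (tex.max() - tex.min())
    ii, jj = np.indices(shape[:2], dtype=float)
    body2d = ((ii - 31.5) / 28) ** 2 + ((jj - 33) / 26) ** 2 <= 1.0
    body = np.repeat(body2d[:, :, None], shape[2], axis=2)
    return np.where(body, 40.0 + 60.0 * tex, 0.0), body
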