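import numpy as np
import pytest

from pyrecond import ModelParams, make_periodic_square
from pyrecond.model_core import FieldState


@pytest.fixture
def default_params():
    return ModelParams()


@pytest.fixture
def small_periodic():
    return make_periodic_square(8.0, 16)


def smooth_random_state(geometry, seed=0, lo=0.05, hi=0.25):
    """A smooth random field state strictly inside the physical domain."""
    rng = np.random.default_rng(seed)
    n = geometry.Nx

    def smooth():
        f = rng.standard_normal((n, n))
        fk = np.fft.fft2(f)
        kx = np.fft.fftfreq(n)
        damp = np.exp(-40.0 * (kx[:, None] ** 2 + kx[None, :] ** 2))
        g = np.real(np.fft.ifft2(fk * damp))
        g = (g - g.min()) / (g.max() - g.min() + 1e-30)
        return lo + (hi - lo) * g

    return FieldState(smooth(), smooth(), 0.0, geometry.h)
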