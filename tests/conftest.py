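import numpy as np
import pytest

from ringuct import (CartesianGrid, LensProfile, TransducerElement,
                     discretize_aperture, make_grid, tone_burst_pulse,
                     water_medium)


@pytest.fixture
def rng():
    return np.random.default_rng(20231017)


@pytest.fixture
def small_grid():
    """Tiny water-scale grid for operator-level property checks."""
    return make_grid((24, 24, 24), 0.4e-3, c_max=1500.0, cfl=0.3,
                     duration=4e-6)


@pytest.fixture
def small_medium(small_grid):
    return water_medium(small_grid.shape)


@pytest.fixture
def pulse_factory():
    def make(dt, center=0.75e6, fmax=1.25e6):
        return tone_burst_pulse(center, dt, max_frequency=fmax)
    return make


@pytest.fixture
def fig2_lens():
    """The full-size parabolic lens (a = 0.014/mm, d0 = 0.45 mm,
    c_lens = 4500 m/s in water)."""
    return LensProfile(curvature=14.0, offset=0.45e-3, lens_sos=4500.0,
                       medium_sos=1500.0)


@pytest.fixture
def discretized_element(small_grid, fig2_lens):
    el = TransducerElement(center=(0.0, 0.0, 0.0), height=3.2e-3,
                           lens=fig2_lens)
    grid = make_grid((32, 32, 32), 0.4e-3, c_max=1500.0, cfl=0.3,
                     duration=4e-6, origin=(-6.4e-3, -6.4e-3, -6.4e-3))
    return discretize_aperture(el, grid, pml_size=8), grid
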