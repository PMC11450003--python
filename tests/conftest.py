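"""Shared fixtures: small, fast simulation setups.

Unit-test simulations run on deliberately coarse grids (dx = 40-50 um)
with matching band limits; physics-accuracy checks at the production
grid spacing live in the acceptance tests.
"""

import dataclasses

import numpy as np
import pytest

from ldvpa import synthetic_data as sd
from ldvpa import wave_engine as we


@pytest.fixture(scope="session")
def ideal_model() -> sd.IQModel:
    return sd.IQModel.ideal()


@pytest.fixture(scope="session")
def distorted_model() -> sd.IQModel:
    """Noiseless version of the default (distorted) detection chain."""
    return dataclasses.replace(sd.IQModel(), noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_phantom() -> sd.PhantomSpec:
    return sd.PhantomSpec(
        thickness=8e-3, channels=[sd.Channel(depth=5e-3)], ink_concentration=1.0
    )


@pytest.fixture(scope="session")
def small_medium(small_phantom) -> we.Medium:
    # 50 um grid; sources used on it are band-limited below ~2 MHz
    return we.build_medium(small_phantom, dx=50e-6, width=6e-3, f_max=2e6)


@pytest.fixture(scope="session")
def tr_setup():
    """Forward simulation of an 80-position scan over a 2 mm channel.

    Shared by localization tests; pressure traces derived from the
    surface velocity via p = Z_s/2 * u.
    """
    from scipy.signal import butter, sosfiltfilt

    dx = 40e-6
    phantom = sd.PhantomSpec(thickness=10e-3, channels=[sd.Channel(depth=7e-3)])
    medium = we.build_medium(phantom, dx=dx, width=11e-3, f_max=2.5e6)
    p0 = sd.initial_pressure_from_absorption(phantom, medium, 40.0)
    positions = (np.arange(80) - 39.5) * 125e-6
    record = we.simulate_forward(medium, p0, 11.5e-6, positions, fs_out=65e6)
    sos = butter(4, 5e6, fs=65e6, output="sos")
    traces = sosfiltfilt(sos, 1.02e6 / 2 * record.velocity, axis=1)
    return {
        "dx": dx,
        "phantom": phantom,
        "medium": medium,
        "positions": positions,
        "record": record,
        "traces": traces,
    }
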