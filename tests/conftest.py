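"""Shared fixtures: presets, initial states and a reusable paced trace."""

import numpy as np
import pytest

from cardioinv.model import Protocol, integrate
from cardioinv.presets import adult_parameters, hipsc_parameters, initial_state


@pytest.fixture(scope="session")
def adult_params():
    return adult_parameters()


@pytest.fixture(scope="session")
def hipsc_params():
    return hipsc_parameters()


@pytest.fixture(scope="session")
def hipsc_initial():
    return initial_state("hipsc")


@pytest.fixture(scope="session")
def adult_initial():
    return initial_state("adult")


@pytest.fixture(scope="session")
def hipsc_beat(hipsc_params, hipsc_initial):
    """One paced hiPSC beat at fine sampling, with currents and fluxes."""
    proto = Protocol(mode="paced", hz=1.0, beats=1, dt=0.02, sample_dt=0.5)
    return integrate(hipsc_params, proto, hipsc_initial)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
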