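import numpy as np
import pytest

from tfrim_sad.simulate import (
    BreathingPattern, ExcitationSpec, SimImpedanceModel, synthesize_recording,
)

# Canonical noise-free RIC phenotype used throughout the oracle tests:
# X(5 Hz) = 2*pi*5*I - 1/(2*pi*5*C) = -0.1387 kPa/(L/s),
# resonant frequency = 1/(2*pi*sqrt(I*C)) = 13.96 Hz.
RIC = dict(R0=0.35, I=0.00065, C=0.20, fdep=0.0, dR_exp=0.0)


@pytest.fixture(scope="session")
def ric_model():
    return SimImpedanceModel(**RIC)


@pytest.fixture(scope="session")
def ric_recording(ric_model):
    """Noise-free stationary recording of the canonical RIC model."""
    return synthesize_recording(ric_model, BreathingPattern(), ExcitationSpec(),
                                fs=400.0, duration=30.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
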