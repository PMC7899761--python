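import numpy as np
import pytest

from emgfatigue.synthgen import (ChannelModel, SessionProtocolSpec,
                                 simulate_session)


@pytest.fixture
def clean_channel() -> ChannelModel:
    """Single noiseless channel with unit gain for exact amplitude checks."""
    return ChannelModel("test_muscle", gain=1.0, center_freq=120.0,
                        alpha=0.8, beta=0.3, noise_floor=0.0)


@pytest.fixture
def quiet_spec() -> SessionProtocolSpec:
    """Noiseless fast-fatiguing protocol (short sessions, exact anchors)."""
    return SessionProtocolSpec(target_level=0.6, gradient=0.02,
                               tremor_sd=0.0, mvc_noise_sd=0.0, seed=7)


@pytest.fixture
def quiet_bundle(quiet_spec):
    return simulate_session(quiet_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
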