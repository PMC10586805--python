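"""Shared fixtures: protocols and generator configs used across the suite."""

import numpy as np
import pytest

from larvahab import GeneratorConfig, StimulusProtocol


@pytest.fixture
def pulse_protocol() -> StimulusProtocol:
    """The reference repeated-pulse stimulus: 500 Hz, Gamma 2, 10 s ON / 20 s OFF."""
    return StimulusProtocol(frequency_hz=500, gamma=2, t_on=10, t_off=20, n_pulses=10)


@pytest.fixture
def continuous_protocol() -> StimulusProtocol:
    return StimulusProtocol.continuous(frequency_hz=500, gamma=2, duration=120.0)


@pytest.fixture
def wildtype_config() -> GeneratorConfig:
    return GeneratorConfig(n_larvae=100, seed=1234)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)
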