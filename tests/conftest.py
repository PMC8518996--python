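import numpy as np
import pytest

from wheezekit import (
    BreathModel,
    DetectorConfig,
    WheezeSpec,
    synthesize_recording,
)


@pytest.fixture(scope="session")
def default_cfg() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture(scope="session")
def breath() -> BreathModel:
    return BreathModel()


@pytest.fixture(scope="session")
def tone_recording(breath):
    """30-s breath-noise recording with one steady 400 Hz / 250 ms wheeze."""
    spec = WheezeSpec(onset_s=5.0, duration_ms=250.0, start_hz=400.0, end_hz=400.0)
    return synthesize_recording(breath, [spec], 30.0, 44100.0, seed=11), spec


@pytest.fixture(scope="session")
def noise_recording(breath):
    """30-s breath-noise-only recording."""
    return synthesize_recording(breath, [], 30.0, 44100.0, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
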