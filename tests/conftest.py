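import numpy as np
import pytest

from knotbp.bpcal import CalibrationModel
from knotbp.synthwave import (
    NoiseSpec,
    ProtocolSegment,
    SessionProtocol,
    simulate_session,
)

FS = 400.0


@pytest.fixture(scope="session")
def true_calib():
    return CalibrationModel(a=-0.5, b=180.0)


@pytest.fixture(scope="session")
def short_protocol():
    """One-minute single-segment protocol for fast waveform tests."""
    return SessionProtocol(
        segments=(ProtocolSegment("sitting", 60.0, 120.0, 80.0, 72.0),),
        sampling_rate=FS,
    )


@pytest.fixture(scope="session")
def noiseless_session(short_protocol, true_calib):
    return simulate_session(short_protocol, NoiseSpec.none(), true_calib)


@pytest.fixture(scope="session")
def posture_session(true_calib):
    """Full three-posture noiseless session (sitting/lying/standing)."""
    return simulate_session(
        SessionProtocol.posture_default(), NoiseSpec.none(), true_calib
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
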