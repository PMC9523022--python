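import numpy as np
import pytest

from cellmech.synthetic import (
    AcquisitionProtocol,
    MechanicalGroundTruth,
    simulate_force_curve,
    simulate_reference_curve,
)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def protocol_volts():
    return AcquisitionProtocol(sensitivity=40e-9)  # 40 nm/V


@pytest.fixture
def homogeneous_truth():
    return MechanicalGroundTruth(modulus_shallow=2400.0)


@pytest.fixture
def clean_curve(homogeneous_truth, protocol):
    """Noise-free homogeneous 2.4 kPa approach curve."""
    return simulate_force_curve(homogeneous_truth, protocol)


@pytest.fixture
def rigid_reference(protocol):
    return simulate_reference_curve(protocol, contact_point=5e-6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
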