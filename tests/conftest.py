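import numpy as np
import pytest

from batmap.phantom import build_neck_phantom, simulate_multiecho
from batmap.protocol import AcquisitionProtocol, FatSpectrum


@pytest.fixture(scope="session")
def nine_peak():
    return FatSpectrum.nine_peak(1.5)


@pytest.fixture(scope="session")
def protocol_small():
    return AcquisitionProtocol(grid_shape=(32, 32, 8))


@pytest.fixture(scope="session")
def truth_small():
    return build_neck_phantom((32, 32, 8), seed=3)


@pytest.fixture(scope="session")
def image_noiseless(truth_small, protocol_small, nine_peak):
    return simulate_multiecho(truth_small, protocol_small, nine_peak, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def image_snr50(truth_small, protocol_small, nine_peak):
    return simulate_multiecho(truth_small, protocol_small, nine_peak, noise_sd=0.02, seed=1)
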