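import numpy as np
import pytest

from raphemap.hrf import GammaHRF
from raphemap.protocol import StimProtocol, make_protocol
from raphemap.synthgen.cohort import GroundTruth


@pytest.fixture(scope="session")
def short_protocol() -> StimProtocol:
    return make_protocol("short")


@pytest.fixture(scope="session")
def long_protocol() -> StimProtocol:
    return make_protocol("long")


@pytest.fixture
def mini_protocol() -> StimProtocol:
    """Three 10 s blocks in a 100-volume scan: cheap for ephys/LFP tests."""
    return StimProtocol(block_onsets=(20.0, 50.0, 80.0), block_duration=10.0,
                        inter_onset=30.0, volume_interval=2.0, n_volumes=60)


@pytest.fixture(scope="session")
def hrf() -> GammaHRF:
    return GammaHRF()


@pytest.fixture
def truth() -> GroundTruth:
    return GroundTruth()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
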