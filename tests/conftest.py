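import numpy as np
import pytest

from sacskit.core import StimProtocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def protocol_40hz():
    """One-minute paradigm: 60 s baseline, 60 s of 40 Hz stimulation, 60 s post."""
    return StimProtocol(
        frequency=40.0, amplitude=100.0, onset=60.0, offset=120.0, sampling_rate=1200.0
    )
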