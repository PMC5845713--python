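import numpy as np
import pytest

from mso_itd.network import NetworkConfig, build_and_run
from mso_itd.stimuli import make_tone


@pytest.fixture(scope="session")
def tone_250():
    """Conditioned 250 Hz, 100 ms, 50 dB SPL diotic tone."""
    return make_tone(250.0, 0.1, 50.0)


@pytest.fixture(scope="session")
def small_run_125():
    """One full-network run: 125 Hz tone, 150 us left-leading ITD.

    Left-leading means the left ear leads, i.e. a negative ITD under the
    positive-equals-right-leading convention.
    """
    stim = make_tone(125.0, 0.1, 50.0, itd=-150e-6)
    net = NetworkConfig(n_per_population=30, cf=125.0, rng_seed=42)
    return build_and_run(stim, net)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
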