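import numpy as np
import pytest

from audithresh import PsychometricObserver, builtin_experiment


@pytest.fixture
def freq_spec():
    return builtin_experiment("freq_disc_tone")


@pytest.fixture
def logistic_observer():
    return PsychometricObserver(alpha=10.0, beta=4.0, gamma=1.0 / 3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
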