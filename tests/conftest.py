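import numpy as np
import pytest

from tapsync import ObserverParams, StimulusCondition


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ci_params():
    return ObserverParams(variant="CI", sigma_p=100.0, p_single=0.6,
                          d=-30.0, beta=0.5, sigma_a=10.0, sigma_b=10.0,
                          sigma_m=10.0)


@pytest.fixture
def dual_condition():
    return StimulusCondition(phase_offset_ms=100.0, jitter_sd_ms=(10.0, 50.0))


@pytest.fixture
def single_condition():
    return StimulusCondition(jitter_sd_ms=10.0, n_streams=1)
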