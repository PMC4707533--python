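import numpy as np
import pytest

from dottrack import ModelParams, make_target_config, sample_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def d4_config():
    return make_target_config("D4")


@pytest.fixture
def d1_config():
    return make_target_config("D1")


@pytest.fixture
def d4_trial(d4_config, rng):
    return sample_trial(d4_config, "right", rng, trial_id="fix_d4")


@pytest.fixture
def easy_params():
    """Moderate-noise parameters that decide quickly on easy trials."""
    return ModelParams(
        sigma_s=40.0, ndt_mu=6.0, ndt_sigma=0.3, bound=0.85,
        prior_left=0.5, lapse_p=0.02, lapse_to_p=0.2,
    )
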