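import dataclasses

import numpy as np
import pytest

from accpulse import DEFAULT_PARAMS, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_free_params():
    """Generator settings with every noise source switched off."""
    return dataclasses.replace(
        DEFAULT_PARAMS,
        ecg_noise_sd_mv=0.0,
        acc_noise_sd_ms2=0.0,
        abp_noise_sd_mmhg=0.0,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A reusable 20 PR + 40 PEA synthetic dataset with ground truth."""
    return generate_dataset(20, 40, seed=777)
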