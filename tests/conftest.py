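import logging

import numpy as np
import pytest

from fmribss.synthetic import SimConfig, assemble_dataset

# estimation-quality warnings (reference lost, empty screens) are expected
# in the deliberately hard regimes some tests exercise
logging.getLogger("fmribss").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    """Tiny but fully featured cohort: 3+2 subjects, 3 sources."""
    return SimConfig(n_hc=3, n_asd=2, k_sources=3, grid_shape=(10, 10, 10),
                     n_timepoints=120, isv_sigma=1.0, amp_sigma=0.1,
                     var_inflation_asd=1.5, inflated_sources=(0,),
                     noise_sigma=0.1, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return assemble_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
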