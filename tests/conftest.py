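import dataclasses

import numpy as np
import pytest

from streamrelay import example_params


@pytest.fixture(scope="session")
def example_dp():
    dp, _ = example_params()
    return dp


@pytest.fixture(scope="session")
def fast_dp(example_dp):
    """Small, quick configuration for engine-level tests: narrow chamber,
    short run, moderate degradation."""
    return dataclasses.replace(example_dp, W=0.2, J=250.0, t_end=0.4,
                               kmax=6.0, record_stride=50)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
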