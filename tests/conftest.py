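import warnings

import numpy as np
import pytest

from seafec.tensor import Tensor


@pytest.fixture(autouse=True)
def _quiet_pool_clamp():
    """Pool sizes larger than desk-scale feature maps clamp with a warning;
    that behaviour has its own test and is noise everywhere else."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="pool size")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def feature_map(rng):
    """Small random (2, 4, 6, 6) feature map."""
    return Tensor(rng.standard_normal((2, 4, 6, 6)).astype(np.float32))
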