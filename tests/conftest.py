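import warnings

import numpy as np
import pytest

from svmswarm import FeatureMatrix, generate_blobs
from svmswarm.data import NoConvergenceWarning


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Truncated dual solves at pathological hyperparameters are expected in
    optimizer sweeps; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NoConvergenceWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs_far():
    """Cleanly separable 2-class clouds."""
    return generate_blobs(n_per_class=20, d=3, separation=10.0, seed=7)


@pytest.fixture
def toy_two_points():
    """The smallest separable problem: x=-1 labeled -1, x=+1 labeled +1."""
    return FeatureMatrix(values=np.array([[-1.0], [1.0]]), labels=np.array([-1, 1]))
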