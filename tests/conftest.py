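import numpy as np
import pytest

import mixselect as mx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dataset2():
    """One realized draw of the 20-exposure correlated design."""
    return mx.simulate_dataset(mx.dataset2_default(), seed=7)


@pytest.fixture
def orthonormal_design(rng):
    """Orthonormal X (X'X = I) with a generic outcome, n=40, p=6."""
    Q, _ = np.linalg.qr(rng.standard_normal((40, 6)))
    y = rng.standard_normal(40)
    return Q, y
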