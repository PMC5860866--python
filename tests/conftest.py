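import numpy as np
import pandas as pd
import pytest

from rsapart import RDM, rdm_from_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rdm(n_items, rng, labels=None):
    """A valid random RDM (squared distances of random points)."""
    pts = rng.standard_normal((n_items, 5))
    d = np.sum((pts[:, None] - pts[None]) ** 2, axis=-1)
    labels = labels or [f"c{i}" for i in range(n_items)]
    return RDM(labels, d)


@pytest.fixture
def rdm12(rng):
    return random_rdm(12, rng)


@pytest.fixture
def feature_rdm(rng):
    X = rng.standard_normal((10, 20))
    return rdm_from_features(pd.DataFrame(X, index=[f"i{k}" for k in range(10)]))
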