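import numpy as np
import pandas as pd
import pytest

from bimix._em import warmup
from bimix.io_preprocess import ExpressionMatrix


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    warmup()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_raw_matrix():
    data = pd.DataFrame(
        [[0.0, 7.0], [1023.0, 3.0], [100.0, 200.0]],
        index=["miR-a", "miR-b", "miR-c"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(data, cohort="tumor", scale="raw")


def planted_mixture(rng, n, mu1, mu2, sigma, pi1):
    """Draw n values from pi1*G(mu1, sigma) + (1-pi1)*G(mu2, sigma)."""
    labels = rng.random(n) >= pi1
    return np.where(labels, rng.normal(mu2, sigma, n), rng.normal(mu1, sigma, n))
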