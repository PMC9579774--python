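import numpy as np
import pytest

from rfmd import RFMDParams


def random_instance(rng, n_max=50, n=None):
    """One random RFMD instance with rates in [0.5, 2] and capacities in
    [0.3, 1] — heterogeneous enough to exercise every code path."""
    if n is None:
        n = int(rng.integers(1, n_max + 1))
    lam = rng.uniform(0.5, 2.0, n + 1)
    q = rng.uniform(0.3, 1.0, n)
    return RFMDParams(lam, q)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
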