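import numpy as np
import pytest

from naipw import Dataset, NuisanceEstimates


@pytest.fixture
def d4():
    """Four-unit worked example: two treated, two controls."""
    ds = Dataset(
        W=np.zeros((4, 2)),
        A=np.array([1.0, 1.0, 0.0, 0.0]),
        Y=np.array([2.0, 0.0, 1.0, 1.0]),
    )
    nu = NuisanceEstimates(
        q1=np.ones(4),
        q0=np.zeros(4),
        g=np.array([0.8, 0.5, 0.5, 0.2]),
    )
    return ds, nu


def random_problem(rng, n=50):
    """A random valid (Dataset, NuisanceEstimates) pair for property tests."""
    while True:
        A = (rng.uniform(size=n) < rng.uniform(0.2, 0.8)).astype(float)
        if 0 < A.sum() < n:
            break
    ds = Dataset(
        W=rng.standard_normal((n, 3)),
        A=A,
        Y=rng.normal(size=n, scale=2.0),
    )
    nu = NuisanceEstimates(
        q1=rng.normal(size=n),
        q0=rng.normal(size=n),
        g=rng.uniform(0.02, 0.98, size=n),
    )
    return ds, nu
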