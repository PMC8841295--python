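import numpy as np
import pytest

from dkipipe.cohort import CohortDesign, default_scheme
from dkipipe.model import (
    DiffusionTensor,
    KurtosisTensor,
    TensorPair,
    isotropic_kurtosis_tensor,
)


@pytest.fixture(scope="session")
def scheme():
    """The study acquisition: 2 b0 + 50 directions at b=1000 and b=2000."""
    return default_scheme()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_tensor_pair(rng, s0=1000.0):
    """A random physically plausible tensor pair (positive-definite D)."""
    md = rng.uniform(0.5e-3, 2.0e-3)
    lam = md * (1.0 + rng.uniform(-0.5, 0.5, 3))
    lam = np.clip(lam, 0.1 * md, None)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    d = q @ np.diag(lam) @ q.T
    k = rng.uniform(0.3, 1.5)
    w = isotropic_kurtosis_tensor(k).to_array()
    # small fully symmetric perturbation
    p = rng.standard_normal((3, 3, 3, 3)) * 0.1 * k
    import itertools

    sym = np.zeros_like(p)
    for perm in itertools.permutations(range(4)):
        sym += np.transpose(p, perm)
    w = w + sym / 24.0
    return TensorPair(
        D=DiffusionTensor.from_matrix(d), W=KurtosisTensor.from_array(w), s0=s0
    )


@pytest.fixture
def small_design():
    """A desk-scale cohort design used by fast end-to-end tests."""
    return CohortDesign(n_per_group=(4, 4), seed=11)
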