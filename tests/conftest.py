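import numpy as np
import pytest
from scipy.stats import special_ortho_group

from dkiasl import default_scheme
from dkiasl.synth import axially_symmetric_tensor
from dkiasl.tensors import kurtosis_tensor_for_constant_k


@pytest.fixture(scope="session")
def scheme():
    """The default 31-volume acquisition: 1 b0 + 15 directions x {1000, 2000}."""
    return default_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_dki_truth(rng, k_range=(0.3, 1.5)):
    """A random plausible voxel ground truth (S0, D, W, MK level)."""
    md = rng.uniform(0.6e-3, 1.2e-3)
    fa = rng.uniform(0.05, 0.6)
    k = rng.uniform(*k_range)
    rot = special_ortho_group.rvs(3, random_state=rng)
    d_mat = rot @ axially_symmetric_tensor(md, fa) @ rot.T
    w_full = kurtosis_tensor_for_constant_k(d_mat, k)
    s0 = rng.uniform(50.0, 200.0)
    return s0, d_mat, w_full, md, fa, k
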