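import numpy as np
import pytest

from rigidnet import simulate
from rigidnet.regression import CohortDesign


@pytest.fixture
def tracking_spec():
    """Moderately underdamped tracker under the standard task conditions."""
    return simulate.TrackingSimSpec(zeta=0.7, omega_n=3.0, seed=11)


@pytest.fixture
def small_var_spec():
    """Three-ROI network with a single strong connection roi0 -> roi1."""
    W = np.zeros((3, 3))
    W[1, 0] = 0.8
    return simulate.NetworkSimSpec(n_rois=3, coeff_matrix=W, n_timepoints=500, seed=5)


def make_design(n, p, support, beta, noise_sd, seed):
    """Random-Gaussian cohort design with a sparse linear score."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    b = np.zeros(p)
    b[list(support)] = beta
    y = X @ b + rng.normal(0.0, noise_sd, size=n)
    return CohortDesign(
        X=X,
        Y=y,
        edge_labels=tuple(f"e{k:03d}" for k in range(p)),
        subject_ids=tuple(f"s{i:03d}" for i in range(n)),
    )
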