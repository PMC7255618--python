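import numpy as np
import pytest

from affectdyn import AIMParameters, OUParameters


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def smooth_unimodal():
    """A gentle single-well landscape used across solver tests."""
    return AIMParameters(
        lambda1=3.0, lambda2=2.0, lambda12=1.0,
        theta1=2.2, theta2=2.4, n1=7.0, n2=8.0, diffusion=3.0e-4,
    )


@pytest.fixture(scope="session")
def isotropic_ou():
    """Symmetric, isotropic OU process well inside the unit square."""
    theta = 0.02
    var_inf = 0.0144
    cov = 2.0 * theta * var_inf * np.eye(2)
    return OUParameters(
        mu=(0.5, 0.5),
        drift_matrix=theta * np.eye(2),
        diffusion_chol=np.linalg.cholesky(cov),
    )


@pytest.fixture(scope="session")
def asymmetric_ou():
    """OU with a non-normal drift matrix (no detailed balance)."""
    b = np.array([[0.03, 0.018], [-0.012, 0.025]])
    cov = np.diag([4e-4, 6e-4])
    return OUParameters(mu=(0.45, 0.55), drift_matrix=b, diffusion_chol=np.linalg.cholesky(cov))
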