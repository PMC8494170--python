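import numpy as np
import pytest

from tdlbm import BasisSpec, RandomEffectConfig
from tdlbm.sim_model import BlockTheta


@pytest.fixture
def padded_spec():
    return BasisSpec.equispaced(n_interior=5, degree=3, domain=(0.0, 1.0),
                                pad=1.0)


@pytest.fixture
def plain_spec():
    return BasisSpec.equispaced(n_interior=5, degree=3, domain=(0.0, 1.0),
                                pad=0.0)


@pytest.fixture
def time_grid():
    return np.linspace(0.0, 1.0, 15)


def make_theta(spec, config_name, beta=None, sigma_diag=(1.0, 0.0, 0.1),
               sigma_eps=0.3, seed=0):
    config = RandomEffectConfig.from_name(config_name)
    rng = np.random.default_rng(seed)
    if beta is None:
        beta = rng.normal(size=spec.n_basis)
    diag = np.array(sigma_diag, dtype=float)
    diag[~config.mask] = 0.0
    return BlockTheta(beta=np.asarray(beta, dtype=float),
                      mu_alpha=np.zeros(3), sigma_alpha=np.diag(diag),
                      sigma_eps=sigma_eps, config=config)


@pytest.fixture
def theta_factory():
    return make_theta
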