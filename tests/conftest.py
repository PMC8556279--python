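import numpy as np
import pytest

from roadpm import DGPParams, ModelSpec, make_lattice, simulate_panel
from roadpm.weights import lattice_queen


@pytest.fixture(scope="session")
def small_geom():
    return make_lattice(5, 5, 10.0)


@pytest.fixture(scope="session")
def small_w(small_geom):
    return lattice_queen(small_geom).row_standardize()


@pytest.fixture(scope="session")
def small_panel(small_geom, small_w):
    """Spatially correlated panel with known parameters on a 5x5 lattice."""
    params = DGPParams(
        beta=(1.0, -0.5),
        regressors=("x1", "x2"),
        lambda_lag=0.4,
        rho_error=0.2,
        sigma_nu=0.6,
        sigma_alpha=0.8,
        covariate_style="standardized",
        seed=11,
    )
    return simulate_panel(small_geom, range(2003, 2011), params, small_w)


@pytest.fixture(scope="session")
def small_spec():
    return ModelSpec(regressors=["x1", "x2"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
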