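import numpy as np
import pytest

from ivcsim import (ActiveParams, PassiveParams, apply_rate_factor,
                    build_lv_mesh)


@pytest.fixture(scope="session")
def coarse_mesh():
    """Smallest admissible LV mesh (224 elements), shared across tests."""
    return build_lv_mesh(n_circ=8, n_long=4)


@pytest.fixture(scope="session")
def passive_params():
    return PassiveParams()


@pytest.fixture(scope="session")
def passive_scaled():
    return apply_rate_factor(PassiveParams())


@pytest.fixture(scope="session")
def active_params():
    return ActiveParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
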