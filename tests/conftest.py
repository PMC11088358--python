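import numpy as np
import pytest

from osteomech.cohort import generate_specimen, load_preset
from osteomech.rheology import RheoParams


@pytest.fixture(scope="session")
def trab_spec():
    return load_preset("table2_trab_ctrl")


@pytest.fixture(scope="session")
def cort_spec():
    return load_preset("table2_cort_ctrl")


@pytest.fixture(scope="session")
def trab_mean_record(trab_spec):
    """Noise-free specimen simulated at the trabecular group-mean parameters."""
    return generate_specimen(trab_spec.param_means, trab_spec.default_protocol(),
                             noise_sd=0.0)


@pytest.fixture(scope="session")
def cort_mean_record(cort_spec):
    """Noise-free specimen simulated at the cortical group-mean parameters."""
    return generate_specimen(cort_spec.param_means, cort_spec.default_protocol(),
                             noise_sd=0.0)


@pytest.fixture()
def elastic_params():
    """Parameters with an unreachable yield stress: purely visco-elastic response."""
    return RheoParams(E_pr=10e9, E_mx=5e9, sigma_y=1e9, sigma_u=1.1e9,
                      p=50.0, eta=5e9, k_D=50.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
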