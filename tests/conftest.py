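import numpy as np
import pytest

from pelvimech import (
    EphysParams,
    MechProtocol,
    SpecimenGeometry,
    TissueMechParams,
    simulate_specimen_mech,
)


@pytest.fixture(scope="session")
def protocol():
    return MechProtocol()


@pytest.fixture(scope="session")
def geometry():
    return SpecimenGeometry()


@pytest.fixture(scope="session")
def noise_free_params():
    return TissueMechParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_trace(noise_free_params, protocol, geometry):
    return simulate_specimen_mech(noise_free_params, protocol, geometry, seed=11)


@pytest.fixture(scope="session")
def linearish_params():
    """Near-linear material: tiny B makes sigma = A*B*eps to 1e-7 relative."""
    return TissueMechParams(A_x=1e5, A_y=1e5, B_x=2e-6, B_y=2e-6, eta=1.0,
                            precond_drop=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def ephys_params():
    return EphysParams()


def make_linear_trace(k=0.2, eta=1.0, seed=5, sample_rate=30.0):
    """Trace of an (effectively) linear material sigma = k*eps (MPa)."""
    B = 2e-6
    params = TissueMechParams(A_x=k / B, A_y=k / B, B_x=B, B_y=B, eta=eta,
                              precond_drop=0.0, noise_sd=0.0)
    proto = MechProtocol(sample_rate=sample_rate)
    return params, simulate_specimen_mech(params, proto, SpecimenGeometry(), seed=seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
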