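import numpy as np
import pytest

from alpsim import (
    FiberROI,
    PhantomGeometry,
    build_phantom,
    control_profile,
    default_protocol,
    esrd_profile,
)


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def roi(geometry):
    return FiberROI.from_geometry(geometry)


@pytest.fixture(scope="session")
def control_field(geometry):
    return build_phantom(geometry, control_profile())


@pytest.fixture(scope="session")
def esrd_field(geometry):
    return build_phantom(geometry, esrd_profile())


def random_spd_tensor(rng, scale=1e-3):
    """Random symmetric positive-definite tensor with DTI-scale entries."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    evals = rng.uniform(0.2, 2.5, size=3) * scale
    return (q * evals) @ q.T
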