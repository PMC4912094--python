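import numpy as np
import pytest
from hypothesis import settings

from helixkink import (
    ErrorModel,
    HelixSpec,
    generate_ideal_helix,
    generate_kinked_helix,
)

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ideal20():
    return generate_ideal_helix(20)


@pytest.fixture(scope="session")
def kinked30():
    return generate_kinked_helix(
        HelixSpec(n_residues=20, kink_angle=30.0, kink_position=9),
        helix_id="kink30",
    )


@pytest.fixture(scope="session")
def published_model():
    return ErrorModel.published_default()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160617)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
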