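import numpy as np
import pytest

from isoniche import Ellipsoid


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_spd(rng, scale=1.0):
    """Random well-conditioned SPD 3x3 matrix."""
    A = rng.standard_normal((3, 3))
    return scale * (A @ A.T + 3.0 * np.eye(3))


def random_rotation(rng):
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def unit_sphere():
    return Ellipsoid(center=np.zeros(3), shape=np.eye(3))
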