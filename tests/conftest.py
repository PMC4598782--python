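import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20150818)


def canonical_helix(P, R, N, n, phase=0.0):
    """Noiseless helix points from the explicit parametric equation."""
    th = np.deg2rad(phase + np.arange(n) * 360.0 / N)
    return np.column_stack(
        [R * np.cos(th), R * np.sin(th), P * th / (2.0 * np.pi)]
    )


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
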