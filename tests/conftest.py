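import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shadow_scene():
    """128x128 textured scene under a sharp flat shadow (ground truth known)."""
    from pxretinex.synthetic_data import make_shadow_scene

    return make_shadow_scene(128, 128, "filtered_noise", 0.3, 4.0, seed=1)


@pytest.fixture(scope="session")
def ramp_scene():
    """128x128 textured scene under a smooth illumination ramp."""
    from pxretinex.synthetic_data import compose, make_illumination, make_texture

    r = make_texture(128, 128, "filtered_noise", 2)
    L = make_illumination(128, 128, "smooth_ramp", low=0.35)
    return compose(r, L)


@pytest.fixture(scope="session")
def checkerboard_scene():
    from pxretinex.synthetic_data import make_checkerboard_shadow

    return make_checkerboard_shadow(128)


def centered_rmse(a, b):
    """Log-domain RMSE after removing the free additive offset."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d - d.mean()
    return float(np.sqrt(np.mean(d * d)))
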