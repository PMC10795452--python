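import numpy as np
import pytest

from st4dseg.phantom import PhantomConfig, generate_phantom


def tiny_config(**overrides):
    """A 32x32x12 phantom that generates in milliseconds for unit tests."""
    defaults = dict(
        extents=(32, 32, 12),
        spacing=(1.5, 1.5, 3.0),
        liver_center=(16.0, 16.0, 6.0),
        liver_semiaxes_mm=(16.0, 14.0, 12.0),
        tumor_center=(18.0, 15.0, 5.5),
        tumor_semiaxes_mm=(6.0, 6.0, 6.0),
        amplitude_si=6.0,
        amplitude_ap=3.0,
        seed=7,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_subject():
    return generate_phantom(tiny_config())


@pytest.fixture(scope="session")
def desk_subject():
    """One default-geometry (64x64x24) subject."""
    return generate_phantom(PhantomConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def numerical_grad(f, x, eps=1e-5):
    """Central-difference gradient of scalar f at float64 array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return g
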