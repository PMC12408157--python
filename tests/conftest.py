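import numpy as np
import pytest

from esegnet.phantoms import PhantomSpec, generate_phantom, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def spec2d():
    return PhantomSpec(dim=2, shape=(64, 64), num_classes=4)


@pytest.fixture(scope="session")
def spec3d():
    return PhantomSpec(dim=3, shape=(32, 32, 16), num_classes=3,
                       spacing=(1.0, 1.0, 2.0))


@pytest.fixture(scope="session")
def sample2d(spec2d):
    return generate_phantom(spec2d, seed=7)


@pytest.fixture(scope="session")
def sample3d(spec3d):
    return generate_phantom(spec3d, seed=7)


@pytest.fixture(scope="session")
def dataset2d(tmp_path_factory, spec2d):
    out = tmp_path_factory.mktemp("ds2d")
    make_dataset(spec2d, 5, seed=42, out_dir=out)
    return out


@pytest.fixture(scope="session")
def dataset3d(tmp_path_factory, spec3d):
    out = tmp_path_factory.mktemp("ds3d")
    make_dataset(spec3d, 5, seed=42, out_dir=out)
    return out


def numerical_gradient(f, x, eps=1e-5):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
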