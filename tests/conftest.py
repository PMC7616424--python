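import numpy as np
import pytest

from calibrax import GeneratorSpec, make_template_dataset


def finite_diff_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x."""
    g = np.zeros_like(x, dtype=np.float64)
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


def rel_err(a: np.ndarray, b: np.ndarray) -> float:
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-12)
    return float(np.abs(a - b).max() / denom)


@pytest.fixture(scope="session")
def tiny_splits():
    """Small separable 4-class dataset shared by training tests."""
    spec = GeneratorSpec(
        num_classes=4, n_train=400, n_val=100, n_test=200, image_size=(16, 16), seed=11
    )
    return make_template_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
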