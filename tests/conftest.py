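import numpy as np
import pytest

from nlinet.data_io import zscore_normalize
from nlinet.synthetic import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic 32x32x16 phantom, z-scored."""
    return zscore_normalize(generate_phantom(PhantomParams(seed=11)))


@pytest.fixture(scope="session")
def raw_phantom_case():
    return generate_phantom(PhantomParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-2) -> np.ndarray:
    """Central-difference gradient of scalar f at x (float32-friendly step)."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
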