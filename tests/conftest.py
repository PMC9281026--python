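import numpy as np
import pytest

from pphpredict.data import Dataset, SynthConfig, generate_pph_like


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cluster_dataset():
    """Perfectly separable two-cluster data: class means at 0 and 8 with
    tiny spread, so any sane classifier reaches accuracy 1."""
    g = np.random.default_rng(7)
    n = 40
    X0 = g.normal(0.0, 0.1, size=(n, 3))
    X1 = g.normal(8.0, 0.1, size=(n, 3))
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n)
    return Dataset(X, y, tuple(f"f{i}" for i in range(3)))


@pytest.fixture
def planted_dataset():
    """Small imbalanced cohort with a known informative subset."""
    ds, informative = generate_pph_like(
        SynthConfig(
            n_samples=400, n_features=12, n_informative=3,
            prevalence=0.3, effect_size=2.0, seed=11,
        )
    )
    return ds, informative


@pytest.fixture
def numerical_gradient():
    """Central finite-difference oracle for gradient checks."""

    def _grad(fn, arr, eps=1e-6):
        out = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            fp = fn()
            arr[i] = orig - eps
            fm = fn()
            arr[i] = orig
            out[i] = (fp - fm) / (2 * eps)
        return out

    return _grad


class StubRng:
    """Replays a fixed sequence of uniform draws (scalars or arrays) and
    integer draws, for tests that pin down a stochastic update exactly."""

    def __init__(self, uniforms, integers=()):
        self._uniforms = list(uniforms)
        self._integers = list(integers)

    def uniform(self, low=0.0, high=1.0, size=None):
        val = self._uniforms.pop(0)
        if size is None:
            return low + (high - low) * float(val)
        return low + (high - low) * np.broadcast_to(np.asarray(val, dtype=float), size if isinstance(size, tuple) else (size,)).copy()

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)


@pytest.fixture
def stub_rng_factory():
    return StubRng
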