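import numpy as np
import pytest

from attrbench.models import MLPRegressor, NetworkSpec


class LinearModel:
    """Exactly linear model f(x) = w.x + b exposed as affine+ReLU layers.

    The single hidden layer is the identity with a large positive bias, so
    its ReLU never clips for the bounded inputs used in tests.
    """

    SHIFT = 1e3

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = float(b)

    def folded_layers(self):
        d = len(self.w)
        hidden = (np.eye(d), np.full(d, self.SHIFT))
        out = (self.w[:, None], np.array([self.b - self.SHIFT * self.w.sum()]))
        return [hidden, out]

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.w + self.b


@pytest.fixture
def linear_model():
    rng = np.random.default_rng(42)
    return LinearModel(rng.standard_normal(12), b=0.7)


@pytest.fixture
def relu_net_factory():
    """Random small ReLU networks (untrained, inference mode)."""

    def make(seed: int, n_features: int = 20, hidden=(16, 12, 8)) -> MLPRegressor:
        spec = NetworkSpec(hidden_sizes=hidden, dropout=0.0, batchnorm=True)
        model = MLPRegressor(n_features, spec, init_seed=seed)
        # randomize running stats so batch-norm folding is non-trivial
        rng = np.random.default_rng(seed + 1)
        model.run_mean = [0.1 * rng.standard_normal(h) for h in hidden]
        model.run_var = [1.0 + 0.2 * rng.random(h) for h in hidden]
        return model

    return make


@pytest.fixture(scope="session")
def std_phenotype():
    """Standardized synthetic phenotype, 60k samples (session-cached)."""
    y = np.random.default_rng(2024).standard_normal(60_000)
    return (y - y.mean()) / y.std()
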