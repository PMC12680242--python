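"""Gradient-based feature attribution for the frozen regression network.

All methods operate on the inference-mode network, where batch
normalization is folded into the affine layers and dropout is off, making
the model an exact stack of affine maps and ReLUs. Attribution is therefore
deterministic given (model, data, seed).

Per-sample scores A_ij are aggregated into per-SNP importance
S_j = mean_i |A_ij| over the attributed samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "AttributionResult",
    "mode_baseline",
    "saliency",
    "integrated_gradients",
    "gradient_shap",
    "deeplift_rescale",
    "smoothgrad",
    "aggregate",
    "compute_attribution",
    "METHODS",
]

_RELU_EPS = 1e-10


@dataclass
class AttributionResult:
    method: str
    smoothing: bool
    scores: np.ndarray      # n_samples x n_features
    importance: np.ndarray  # n_features

    @property
    def variant(self) -> str:
        return f"{self.method}{'+sg' if self.smoothing else ''}"


def aggregate(scores: np.ndarray) -> np.ndarray:
    """Per-feature importance: mean absolute per-sample attribution."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 0:
        raise ConfigurationError("cannot aggregate over an empty sample set")
    return np.abs(scores).mean(axis=0)


def mode_baseline(X_train: np.ndarray) -> np.ndarray:
    """Per-feature mode genotype over the training split (values in {0,1,2})."""
    X = np.asarray(X_train)
    counts = np.stack([(X == v).sum(axis=0) for v in (0, 1, 2)])
    return counts.argmax(axis=0).astype(float)


def _layers(model) -> list[tuple[np.ndarray, np.ndarray]]:
    if not hasattr(model, "folded_layers"):
        raise ConfigurationError(
            "unsupported architecture: model must expose folded affine+ReLU layers"
        )
    return model.folded_layers()


def _forward(layers, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass returning the scalar output and hidden pre-activations."""
    a = X
    pres = []
    for A, c in layers[:-1]:
        pre = a @ A + c
        pres.append(pre)
        a = np.maximum(pre, 0.0)
    A, c = layers[-1]
    return (a @ A + c)[:, 0], pres


def _grad_input(layers, X: np.ndarray) -> np.ndarray:
    """Gradient of the scalar output w.r.t. each input row; shape like X."""
    _, pres = _forward(layers, X)
    A_out, _ = layers[-1]
    g = np.broadcast_to(A_out[:, 0], (X.shape[0], A_out.shape[0])).copy()
    for (A, _), pre in zip(reversed(layers[:-1]), reversed(pres)):
        g = (g * (pre > 0)) @ A.T
    return g


def _result(method: str, scores: np.ndarray) -> AttributionResult:
    return AttributionResult(method, False, scores, aggregate(scores))


def saliency(model, X: np.ndarray, global_flag: bool = True) -> AttributionResult:
    """Input gradient; with ``global_flag`` scaled elementwise by the input."""
    X = np.asarray(X, dtype=float)
    g = _grad_input(_layers(model), X)
    return _result("saliency", g * X if global_flag else g)


def integrated_gradients(
    model,
    X: np.ndarray,
    baseline: np.ndarray,
    n_steps: int = 50,
) -> AttributionResult:
    """Midpoint-Riemann path integral of gradients from baseline to input.

    Satisfies completeness sum_j A_j ~= f(x) - f(x') with error shrinking in
    ``n_steps`` (exact for linear models at any step count).
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    X = np.asarray(X, dtype=float)
    baseline = np.broadcast_to(np.asarray(baseline, dtype=float), X.shape)
    layers = _layers(model)
    delta = X - baseline
    total = np.zeros_like(X)
    for k in range(n_steps):
        alpha = (k + 0.5) / n_steps
        total += _grad_input(layers, baseline + alpha * delta)
    return _result("integrated_gradients", delta * total / n_steps)


def gradient_shap(
    model,
    X: np.ndarray,
    baseline: np.ndarray,
    n_samples: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AttributionResult:
    """Monte Carlo expected-gradients estimate over a jittered baseline.

    Each draw jitters the baseline with Gaussian noise, picks a uniform
    point on the baseline-to-input path, and accumulates
    (x - x') * grad f at that point.
    """
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    X = np.asarray(X, dtype=float)
    base = np.broadcast_to(np.asarray(baseline, dtype=float), X.shape)
    layers = _layers(model)
    rng = np.random.default_rng(seed)
    total = np.zeros_like(X)
    for _ in range(n_samples):
        b = base + noise_sd * rng.standard_normal(X.shape) if noise_sd > 0 else base
        alpha = rng.random((X.shape[0], 1))
        point = b + alpha * (X - b)
        total += (X - b) * _grad_input(layers, point)
    return _result("gradient_shap", total / n_samples)


def deeplift_rescale(model, X: np.ndarray, baseline: np.ndarray) -> AttributionResult:
    """Rescale-rule contributions relative to the baseline.

    Multipliers through affine layers are the layer matrices; through each
    ReLU the multiplier is delta-out / delta-in (falling back to the local
    derivative where delta-in vanishes). Contributions satisfy
    summation-to-delta exactly on affine+ReLU networks.
    """
    X = np.asarray(X, dtype=float)
    layers = _layers(model)
    base = np.broadcast_to(np.asarray(baseline, dtype=float), X.shape)
    _, pres_x = _forward(layers, X)
    _, pres_b = _forward(layers, base)
    A_out, _ = layers[-1]
    m = np.broadcast_to(A_out[:, 0], (X.shape[0], A_out.shape[0])).copy()
    for (A, _), pre_x, pre_b in zip(reversed(layers[:-1]), reversed(pres_x), reversed(pres_b)):
        d_in = pre_x - pre_b
        d_out = np.maximum(pre_x, 0.0) - np.maximum(pre_b, 0.0)
        mult = np.where(np.abs(d_in) > _RELU_EPS, d_out / np.where(d_in == 0, 1.0, d_in),
                        (pre_x > 0).astype(float))
        m = (m * mult) @ A.T
    return _result("deeplift", m * (X - base))


def smoothgrad(
    base_method,
    model,
    X: np.ndarray,
    n_noise: int = 5,
    noise_sd=0.1,
    seed: int = 0,
    **kwargs,
) -> AttributionResult:
    """Average ``base_method`` attributions over Gaussian-perturbed inputs.

    ``noise_sd`` may be a scalar or a per-feature vector (e.g. 0.1x the
    training-set feature standard deviations).
    """
    if n_noise < 1:
        raise ConfigurationError("n_noise must be >= 1")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    sd = np.asarray(noise_sd, dtype=float)
    total = None
    method_name = None
    for _ in range(n_noise):
        noisy = X + sd * rng.standard_normal(X.shape)
        res = base_method(model, noisy, **kwargs)
        method_name = res.method
        total = res.scores if total is None else total + res.scores
    scores = total / n_noise
    return AttributionResult(method_name, True, scores, aggregate(scores))


#: method registry used by the benchmark orchestrator
METHODS = ("saliency", "gradient_shap", "deeplift", "integrated_gradients")


def compute_attribution(
    method: str,
    model,
    X: np.ndarray,
    baseline: np.ndarray,
    smoothing: bool = False,
    n_steps: int = 50,
    shap_samples: int = 5,
    shap_noise_sd: float = 0.0,
    sg_noise: int = 5,
    sg_noise_sd=0.1,
    seed: int = 0,
    saliency_global: bool = True,
) -> AttributionResult:
    """Dispatch one method x smoothing variant with shared defaults."""
    if method == "saliency":
        fn = lambda m, x: saliency(m, x, global_flag=saliency_global)  # noqa: E731
    elif method == "gradient_shap":
        fn = lambda m, x: gradient_shap(  # noqa: E731
            m, x, baseline, n_samples=shap_samples, noise_sd=shap_noise_sd, seed=seed
        )
    elif method == "deeplift":
        fn = lambda m, x: deeplift_rescale(m, x, baseline)  # noqa: E731
    elif method == "integrated_gradients":
        fn = lambda m, x: integrated_gradients(m, x, baseline, n_steps=n_steps)  # noqa: E731
    else:
        raise ConfigurationError(f"unknown attribution method {method!r}")
    if smoothing:
        return smoothgrad(fn, model, X, n_noise=sg_noise, noise_sd=sg_noise_sd, seed=seed + 1)
    return fn(model, np.asarray(X, dtype=float))
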