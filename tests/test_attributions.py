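import numpy as np
import pytest

from attrbench import attributions as attr
from attrbench.errors import ConfigurationError

rng = np.random.default_rng(123)


@pytest.fixture
def X12():
    return rng.standard_normal((8, 12))


class TestModeBaseline:
    def test_mode_per_feature(self):
        X = np.array([[0, 1, 2], [0, 1, 2], [1, 2, 2], [2, 0, 1]])
        assert np.array_equal(attr.mode_baseline(X), [0.0, 1.0, 2.0])

    def test_values_in_domain(self):
        X = rng.integers(0, 3, size=(50, 10))
        b = attr.mode_baseline(X)
        assert set(np.unique(b)) <= {0.0, 1.0, 2.0}


class TestSaliency:
    def test_linear_gradient_is_w(self, linear_model, X12):
        res = attr.saliency(linear_model, X12, global_flag=False)
        assert np.allclose(res.scores, np.tile(linear_model.w, (8, 1)))

    def test_global_flag_multiplies_input(self, linear_model, X12):
        res = attr.saliency(linear_model, X12, global_flag=True)
        assert np.allclose(res.scores, linear_model.w * X12)

    def test_constant_model_zero(self, X12):
        from conftest import LinearModel

        res = attr.saliency(LinearModel(np.zeros(12)), X12, global_flag=False)
        assert np.allclose(res.scores, 0.0)


class TestIntegratedGradients:
    def test_linear_exact_any_steps(self, linear_model, X12):
        baseline = np.zeros(12)
        for steps in (1, 3, 50):
            res = attr.integrated_gradients(linear_model, X12, baseline, n_steps=steps)
            assert np.allclose(res.scores, X12 * linear_model.w, atol=1e-10)

    def test_input_equals_baseline_is_zero(self, linear_model):
        baseline = np.full(12, 0.5)
        X = np.tile(baseline, (3, 1))
        res = attr.integrated_gradients(linear_model, X, baseline)
        assert np.allclose(res.scores, 0.0)

    def test_completeness_on_relu_net(self, relu_net_factory):
        model = relu_net_factory(0)
        X = rng.standard_normal((6, 20))
        baseline = np.zeros(20)
        res = attr.integrated_gradients(model, X, baseline, n_steps=512)
        delta = model.predict(X) - model.predict(baseline[None, :])
        assert np.max(np.abs(res.scores.sum(axis=1) - delta)) < 1e-3

    def test_invalid_steps(self, linear_model, X12):
        with pytest.raises(ConfigurationError):
            attr.integrated_gradients(linear_model, X12, np.zeros(12), n_steps=0)


class TestGradientShap:
    def test_linear_closed_form_within_mc_error(self, linear_model, X12):
        noise_sd, n_samples = 0.3, 400
        res = attr.gradient_shap(linear_model, X12, np.zeros(12),
                                 n_samples=n_samples, noise_sd=noise_sd, seed=0)
        expected = X12 * linear_model.w
        se = noise_sd * np.abs(linear_model.w) / np.sqrt(n_samples)
        assert np.all(np.abs(res.scores - expected) <= 3 * se + 1e-12)

    def test_reproducible(self, linear_model, X12):
        a = attr.gradient_shap(linear_model, X12, np.zeros(12), n_samples=1, seed=7)
        b = attr.gradient_shap(linear_model, X12, np.zeros(12), n_samples=1, seed=7)
        assert np.array_equal(a.scores, b.scores)

    def test_degenerate_equals_ig_on_linear(self, linear_model, X12):
        baseline = np.zeros(12)
        gs = attr.gradient_shap(linear_model, X12, baseline, n_samples=1, noise_sd=0.0, seed=1)
        ig = attr.integrated_gradients(linear_model, X12, baseline, n_steps=4)
        assert np.allclose(gs.scores, ig.scores, atol=1e-10)


class TestDeepLift:
    def test_linear_closed_form(self, linear_model, X12):
        baseline = np.full(12, 1.0)
        res = attr.deeplift_rescale(linear_model, X12, baseline)
        assert np.allclose(res.scores, (X12 - baseline) * linear_model.w, atol=1e-10)

    def test_summation_to_delta(self, relu_net_factory):
        for seed in range(5):
            model = relu_net_factory(seed)
            X = np.random.default_rng(seed).standard_normal((10, 20))
            baseline = np.random.default_rng(seed + 100).integers(0, 3, 20).astype(float)
            res = attr.deeplift_rescale(model, X, baseline)
            delta = model.predict(X) - model.predict(baseline[None, :])
            assert np.max(np.abs(res.scores.sum(axis=1) - delta)) < 1e-6

    def test_input_equals_baseline_is_zero(self, relu_net_factory):
        model = relu_net_factory(3)
        baseline = np.ones(20)
        res = attr.deeplift_rescale(model, np.tile(baseline, (2, 1)), baseline)
        assert np.allclose(res.scores, 0.0)

    def test_unsupported_model_rejected(self):
        with pytest.raises(ConfigurationError):
            attr.deeplift_rescale(object(), np.zeros((1, 3)), np.zeros(3))


class TestSmoothGrad:
    def test_zero_noise_identity(self, relu_net_factory):
        model = relu_net_factory(1)
        X = rng.standard_normal((4, 20))
        base = lambda m, x: attr.saliency(m, x, global_flag=False)  # noqa: E731
        sg = attr.smoothgrad(base, model, X, n_noise=3, noise_sd=0.0, seed=0)
        assert np.allclose(sg.scores, base(model, X).scores)
        assert sg.smoothing is True

    def test_linear_gradient_unchanged_by_noise(self, linear_model, X12):
        base = lambda m, x: attr.saliency(m, x, global_flag=False)  # noqa: E731
        sg = attr.smoothgrad(base, linear_model, X12, n_noise=10, noise_sd=0.5, seed=1)
        assert np.allclose(sg.scores, np.tile(linear_model.w, (8, 1)))

    def test_variance_reduction(self, relu_net_factory):
        model = relu_net_factory(2)
        x = rng.standard_normal((1, 20))
        base = lambda m, z: attr.saliency(m, z, global_flag=False)  # noqa: E731
        noisy = [base(model, x + 0.5 * np.random.default_rng(k).standard_normal(x.shape)).scores
                 for k in range(40)]
        smooth = [attr.smoothgrad(base, model, x, n_noise=50, noise_sd=0.5, seed=k).scores
                  for k in range(10)]
        assert np.var(np.stack(smooth), axis=0).mean() < np.var(np.stack(noisy), axis=0).mean()

    def test_per_feature_noise_vector_accepted(self, linear_model, X12):
        sd = np.linspace(0, 1, 12)
        base = lambda m, x: attr.saliency(m, x, global_flag=False)  # noqa: E731
        sg = attr.smoothgrad(base, linear_model, X12, n_noise=2, noise_sd=sd, seed=2)
        assert sg.scores.shape == X12.shape


class TestAggregate:
    def test_single_sample(self):
        A = np.array([[1.0, -2.0, 0.5]])
        assert np.array_equal(attr.aggregate(A), [1.0, 2.0, 0.5])

    def test_sign_invariance(self):
        A = rng.standard_normal((6, 4))
        assert np.allclose(attr.aggregate(A), attr.aggregate(-A))

    def test_matches_brute_force(self):
        A = rng.standard_normal((50, 9))
        brute = np.array([np.mean([abs(A[i, j]) for i in range(50)]) for j in range(9)])
        assert np.allclose(attr.aggregate(A), brute, atol=1e-10)

    def test_importance_attached_to_results(self, linear_model, X12):
        res = attr.saliency(linear_model, X12)
        assert np.allclose(res.importance, np.abs(res.scores).mean(axis=0), atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            attr.aggregate(np.empty((0, 3)))


class TestLinearEquivalence:
    """On f(x) = w.x + b all baseline methods agree with (x - x') * w."""

    def test_all_methods_agree(self, linear_model, X12):
        baseline = np.full(12, 2.0)
        expected = (X12 - baseline) * linear_model.w
        ig = attr.integrated_gradients(linear_model, X12, baseline, n_steps=8)
        dl = attr.deeplift_rescale(linear_model, X12, baseline)
        gs = attr.gradient_shap(linear_model, X12, baseline, n_samples=64, noise_sd=0.0, seed=0)
        assert np.allclose(ig.scores, expected, atol=1e-10)
        assert np.allclose(dl.scores, expected, atol=1e-10)
        assert np.allclose(gs.scores, expected, atol=1e-10)  # exact: gradient constant


class TestDispatch:
    def test_unknown_method(self, linear_model, X12):
        with pytest.raises(ConfigurationError):
            attr.compute_attribution("lime", linear_model, X12, np.zeros(12))

    def test_all_registered_methods_run(self, relu_net_factory):
        model = relu_net_factory(4)
        X = rng.standard_normal((3, 20))
        baseline = np.zeros(20)
        for method in attr.METHODS:
            for smoothing in (False, True):
                res = attr.compute_attribution(method, model, X, baseline,
                                               smoothing=smoothing, seed=5)
                assert res.scores.shape == X.shape
                assert res.smoothing == smoothing

    def test_deterministic_given_seed(self, relu_net_factory):
        model = relu_net_factory(5)
        X = rng.standard_normal((3, 20))
        for method in attr.METHODS:
            a = attr.compute_attribution(method, model, X, np.zeros(20), smoothing=True, seed=9)
            b = attr.compute_attribution(method, model, X, np.zeros(20), smoothing=True, seed=9)
            assert np.array_equal(a.scores, b.scores)
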