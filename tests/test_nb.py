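import numpy as np
import pytest
from scipy.stats import norm

from drowsyhog.errors import FitError, ParameterError
from drowsyhog.nb import (
    NBModel,
    fit_bernoulli_nb,
    fit_gaussian_nb,
    load_model,
    log_likelihood,
    predict_map,
    predict_map_batch,
    predict_ml,
    save_model,
)


class TestFitBernoulli:
    def test_m_estimate_arithmetic(self):
        # class a: n=4 samples, feature set in 3 of them -> (3 + 2*0.5)/(4 + 2) = 2/3
        X = np.array([[1], [1], [1], [0], [0], [0]])
        y = ["a", "a", "a", "a", "b", "b"]
        model = fit_bernoulli_nb(X, y, m_weight=2.0)
        ja = model.classes.index("a")
        assert model.p1[ja, 0] == pytest.approx(2 / 3, abs=1e-12)

    def test_priors_are_class_frequencies(self):
        X = np.zeros((10, 2), dtype=int)
        y = ["a"] * 6 + ["b"] * 4
        model = fit_bernoulli_nb(X, y)
        assert np.allclose(model.priors, [0.6, 0.4], atol=1e-12)
        assert model.priors.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unseen_feature_still_positive_probability(self):
        # n=5, n_c=0 -> (0 + 2*0.5)/(5 + 2) = 1/7
        X = np.vstack([np.zeros((5, 1), dtype=int), np.ones((3, 1), dtype=int)])
        y = ["a"] * 5 + ["b"] * 3
        model = fit_bernoulli_nb(X, y)
        ja = model.classes.index("a")
        assert model.p1[ja, 0] == pytest.approx(1 / 7, abs=1e-12)

    def test_smoothed_parameters_strictly_inside_unit_interval(self, rng):
        X = rng.integers(0, 2, (30, 16))
        y = rng.choice(["a", "b"], 30).tolist() + []
        y[0], y[1] = "a", "b"  # both classes present
        model = fit_bernoulli_nb(X, y)
        assert np.all(model.p1 > 0) and np.all(model.p1 < 1)

    def test_non_binary_features_rejected(self):
        with pytest.raises(TypeError):
            fit_bernoulli_nb(np.array([[0.5], [1.0]]), ["a", "b"])

    def test_single_class_rejected(self):
        with pytest.raises(FitError):
            fit_bernoulli_nb(np.zeros((3, 2), dtype=int), ["a", "a", "a"])

    def test_parameter_count(self):
        X = np.random.default_rng(0).integers(0, 2, (10, 20))
        y = ["a"] * 5 + ["b"] * 5
        model = fit_bernoulli_nb(X, y)
        assert model.parameter_count() == 2 * 20 + 1


class TestFitGaussian:
    def test_population_moments(self):
        X = np.array([[1.0], [2.0], [3.0], [0.0], [0.0]])
        y = ["a", "a", "a", "b", "b"]
        model = fit_gaussian_nb(X, y)
        ja = model.classes.index("a")
        assert model.mu[ja, 0] == pytest.approx(2.0, abs=1e-12)
        assert model.var[ja, 0] == pytest.approx(2 / 3, abs=1e-12)

    def test_constant_feature_hits_variance_floor(self):
        X = np.array([[5.0], [5.0], [5.0], [1.0], [2.0]])
        y = ["a", "a", "a", "b", "b"]
        model = fit_gaussian_nb(X, y)
        ja = model.classes.index("a")
        assert model.var[ja, 0] == pytest.approx(1e-9)

    def test_parameter_recovery_at_n1000(self):
        rng = np.random.default_rng(0)
        mu_true = {"a": -1.0, "b": 1.0}
        sd_true = 1.0
        X = np.vstack([rng.normal(mu_true["a"], sd_true, (1000, 4)),
                       rng.normal(mu_true["b"], sd_true, (1000, 4))])
        y = ["a"] * 1000 + ["b"] * 1000
        model = fit_gaussian_nb(X, y)
        for j, c in enumerate(model.classes):
            assert np.all(np.abs(model.mu[j] - mu_true[c]) / abs(mu_true[c]) < 0.05)
            assert np.all(np.abs(np.sqrt(model.var[j]) - sd_true) / sd_true < 0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(FitError):
            fit_gaussian_nb(np.array([[1.0], [2.0], [3.0]]), ["a", "b", "b"])


class TestLogLikelihood:
    def test_gaussian_at_mode_unit_sigma(self):
        X = np.array([[0.0], [0.0], [1.0], [-1.0]])
        y = ["a", "a", "b", "b"]
        model = fit_gaussian_nb(X, y)
        model.mu = np.array([[0.0], [5.0]])
        model.var = np.array([[1.0], [1.0]])
        assert log_likelihood(model, np.array([0.0]), 0) == pytest.approx(-0.9189385, abs=1e-6)

    def test_symmetric_bernoulli_model(self):
        model = NBModel(kind="bernoulli", classes=["a", "b"], priors=np.array([0.5, 0.5]),
                        n_features=10, p1=np.full((2, 10), 0.5))
        x = np.random.default_rng(1).integers(0, 2, 10)
        assert log_likelihood(model, x, 0) == pytest.approx(10 * np.log(0.5), abs=1e-12)

    def test_log_space_matches_direct_product(self, rng):
        for _ in range(20):
            X = rng.integers(0, 2, (8, 5))
            y = ["a"] * 4 + ["b"] * 4
            model = fit_bernoulli_nb(X, y)
            x = rng.integers(0, 2, 5)
            direct = np.prod([model.p1[0, i] if x[i] else 1 - model.p1[0, i] for i in range(5)])
            assert np.exp(log_likelihood(model, x, 0)) == pytest.approx(direct, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = NBModel(kind="bernoulli", classes=["a", "b"], priors=np.array([0.5, 0.5]),
                        n_features=4, p1=np.full((2, 4), 0.5))
        with pytest.raises(ParameterError):
            log_likelihood(model, np.zeros(3), 0)


class TestPredict:
    @staticmethod
    def symmetric_model():
        return NBModel(kind="gaussian", classes=["a", "b"], priors=np.array([0.5, 0.5]),
                       n_features=1, mu=np.array([[-1.0], [1.0]]), var=np.array([[1.0], [1.0]]))

    def test_exact_tie_breaks_to_lowest_index(self):
        pred = predict_map(self.symmetric_model(), np.array([0.0]))
        assert pred.label == "a"
        assert np.allclose(pred.posterior, [0.5, 0.5])

    def test_posterior_sums_to_one(self, rng):
        X = rng.integers(0, 2, (20, 12))
        y = ["a"] * 10 + ["b"] * 10
        model = fit_bernoulli_nb(X, y)
        for _ in range(25):
            pred = predict_map(model, rng.integers(0, 2, 12))
            assert pred.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_equal_priors_make_ml_equal_map(self, rng):
        X = rng.normal(0, 1, (40, 3)) + np.array([2.0, 0, -2])
        y = ["a"] * 20 + ["b"] * 20
        model = fit_gaussian_nb(X, y)
        for _ in range(30):
            x = rng.normal(0, 2, 3)
            assert predict_ml(model, x).label == predict_map(model, x).label

    def test_skewed_priors_separate_map_from_ml(self):
        model = self.symmetric_model()
        model.priors = np.array([0.1, 0.9])
        x = np.array([0.0])  # equidistant in likelihood
        assert predict_map(model, x).label == "b"  # prior decides
        assert predict_ml(model, x).label == "a"  # tie -> lowest index

    def test_agreement_with_sklearn_gaussian_nb(self, rng):
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        X = rng.normal(0, 1, (300, 6))
        X[:150] += 1.0
        y = np.array(["a"] * 150 + ["b"] * 150)
        model = fit_gaussian_nb(X, y)
        ref = sklearn_nb.GaussianNB(var_smoothing=0.0).fit(X, y)
        Xtest = rng.normal(0.5, 1.5, (500, 6))
        labels, posts = predict_map_batch(model, Xtest)
        assert np.array_equal(labels.astype(str), ref.predict(Xtest))
        assert np.allclose(posts, ref.predict_proba(Xtest), atol=1e-6)

    def test_separable_classes_near_perfect_accuracy(self, rng):
        X = np.vstack([rng.normal(-5, 1, (1000, 4)), rng.normal(5, 1, (1000, 4))])
        y = np.array(["a"] * 1000 + ["b"] * 1000)
        model = fit_gaussian_nb(X, y)
        labels, _ = predict_map_batch(model, X)
        assert np.mean(labels.astype(str) == y) >= 0.99

    def test_bayes_optimal_accuracy_approached(self, rng):
        # independent unit-variance Gaussians, means +-0.5 in 4 dims:
        # optimal accuracy = Phi(d/2) with d = 2.
        d = 2.0
        bayes = norm.cdf(d / 2)
        Xtr = np.vstack([rng.normal(-0.5, 1, (1000, 4)), rng.normal(0.5, 1, (1000, 4))])
        ytr = np.array(["a"] * 1000 + ["b"] * 1000)
        model = fit_gaussian_nb(Xtr, ytr)
        Xte = np.vstack([rng.normal(-0.5, 1, (5000, 4)), rng.normal(0.5, 1, (5000, 4))])
        yte = np.array(["a"] * 5000 + ["b"] * 5000)
        labels, _ = predict_map_batch(model, Xte)
        acc = np.mean(labels.astype(str) == yte)
        assert abs(acc - bayes) < 0.02


class TestModelSerialization:
    def test_bernoulli_roundtrip_identical_predictions(self, rng, tmp_path):
        X = rng.integers(0, 2, (30, 40))
        y = ["open"] * 15 + ["closed"] * 15
        model = fit_bernoulli_nb(X, y)
        model.layout = {"scheme": "bosh", "patch_w": 64}
        path = tmp_path / "model.txt"
        save_model(path, model)
        loaded = load_model(path)
        assert loaded.classes == model.classes
        assert loaded.layout == model.layout
        Xq = rng.integers(0, 2, (100, 40))
        l1, p1 = predict_map_batch(model, Xq)
        l2, p2 = predict_map_batch(loaded, Xq)
        assert np.array_equal(l1, l2)
        assert np.array_equal(p1, p2)  # bit-identical, repr round-trip

    def test_gaussian_roundtrip(self, rng, tmp_path):
        X = rng.normal(0, 1, (20, 6))
        y = ["a"] * 10 + ["b"] * 10
        model = fit_gaussian_nb(X, y)
        path = tmp_path / "model.txt"
        save_model(path, model)
        loaded = load_model(path)
        assert np.array_equal(loaded.mu, model.mu)
        assert np.array_equal(loaded.var, model.var)
        assert np.array_equal(loaded.priors, model.priors)
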