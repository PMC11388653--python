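import numpy as np
import pytest

from mgx.classifiers import (
    TrainedClassifier,
    bldc_discriminants,
    bldc_fit,
    bldc_predict,
    fit_classifier,
    gini,
    info_gain,
    majority_vote,
    nbc_fit,
    nbc_log_posterior,
    nbc_predict,
    rbf_kernel,
)
from mgx.errors import FitError, InputError, PredictError
from mgx.io_formats import ADENO, MESO, RunConfig

ALL_KINDS = ("BLDC", "NBC", "RFC", "DTC", "SVM_linear", "SVM_poly", "SVM_rbf")


def _two_gaussians(rng, n=40, sep=2.0, dim=2):
    Xa = rng.standard_normal((n, dim)) + sep
    Xm = rng.standard_normal((n // 2, dim)) - sep
    X = np.vstack([Xa, Xm])
    y = np.array([ADENO] * n + [MESO] * (n // 2))
    return X, y


class TestBldc:
    def test_symmetric_classes_put_boundary_at_zero(self, rng):
        Xa = rng.normal(1.0, 0.3, size=(200, 1))
        Xm = rng.normal(-1.0, 0.3, size=(200, 1))
        model = bldc_fit(np.vstack([Xa, Xm]), np.array([ADENO] * 200 + [MESO] * 200))
        label, _ = bldc_predict(model, [0.5])
        assert label == ADENO
        label, _ = bldc_predict(model, [-0.5])
        assert label == MESO

    def test_identical_class_distributions_decided_by_prior(self, rng):
        X = rng.standard_normal((100, 2))
        X2 = X.copy()
        y = np.array([ADENO] * 100 + [MESO] * 100)
        model = bldc_fit(np.vstack([X, X2]), y, priors={ADENO: 0.9, MESO: 0.1})
        label, g = bldc_predict(model, X[0])
        assert label == ADENO
        assert g[ADENO] > g[MESO]

    def test_discriminant_matches_explicit_equation_oracle(self, rng):
        X, y = _two_gaussians(rng, n=30)
        model = bldc_fit(X, y, ridge=1e-3)
        x = rng.standard_normal(2)
        g = bldc_discriminants(model, x[None, :])[0]
        for j, c in enumerate(model.classes):
            # independently coded discriminant
            cov = np.linalg.inv(model.inv_covs[c])
            d = x - model.means[c]
            g_oracle = (-0.5 * np.linalg.slogdet(cov)[1]
                        - 0.5 * d @ np.linalg.solve(cov, d)
                        + model.log_priors[c])
            assert g[j] == pytest.approx(g_oracle, abs=1e-8)

    def test_uniform_prior_scaling_leaves_predictions_unchanged(self, rng):
        X, y = _two_gaussians(rng)
        a = bldc_fit(X, y, priors={ADENO: 0.5, MESO: 0.5})
        b = bldc_fit(X, y, priors={ADENO: 2.0, MESO: 2.0})  # unnormalized, equal
        probe = rng.standard_normal((20, 2))
        np.testing.assert_array_equal(bldc_discriminants(a, probe).argmax(axis=1),
                                      bldc_discriminants(b, probe).argmax(axis=1))

    def test_prediction_invariant_to_consistent_feature_reordering(self, rng):
        X, y = _two_gaussians(rng, dim=4)
        perm = np.array([2, 0, 3, 1])
        m1 = bldc_fit(X, y)
        m2 = bldc_fit(X[:, perm], y)
        probe = rng.standard_normal((10, 4))
        np.testing.assert_allclose(bldc_discriminants(m1, probe),
                                   bldc_discriminants(m2, probe[:, perm]), atol=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _two_gaussians(rng)
        model = bldc_fit(X, y)
        with pytest.raises(PredictError):
            bldc_predict(model, [1.0, 2.0, 3.0])

    def test_absent_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(FitError):
            bldc_fit(X, np.array([ADENO] * 10))


class TestNbc:
    def test_equidistant_point_decided_by_prior(self, rng):
        Xa = rng.normal(0.0, 1.0, size=(5000, 1))
        Xm = rng.normal(4.0, 1.0, size=(5000, 1))
        y = np.array([ADENO] * 5000 + [MESO] * 5000)
        model = nbc_fit(np.vstack([Xa, Xm]), y, priors={ADENO: 0.7, MESO: 0.3})
        label, _ = nbc_predict(model, [2.0])
        assert label == ADENO  # prior tie-break at the midpoint

    def test_log_posterior_matches_product_oracle(self, rng):
        import scipy.stats

        X, y = _two_gaussians(rng, n=30, dim=3)
        model = nbc_fit(X, y, smoothing=0.01)
        x = rng.standard_normal(3)
        lp = nbc_log_posterior(model, x[None, :])[0]
        for j, c in enumerate(model.classes):
            # brute-force per-feature product, in log space
            ll = sum(scipy.stats.norm.logpdf(x[k], model.means[c][k],
                                             np.sqrt(model.variances[c][k]))
                     for k in range(3))
            assert lp[j] == pytest.approx(ll + model.log_priors[c], abs=1e-8)

    def test_duplicating_training_set_leaves_parameters_unchanged(self, rng):
        X, y = _two_gaussians(rng)
        m1 = nbc_fit(X, y)
        m2 = nbc_fit(np.vstack([X, X]), np.concatenate([y, y]))
        for c in m1.classes:
            np.testing.assert_allclose(m1.means[c], m2.means[c], atol=1e-12)
            np.testing.assert_allclose(m1.variances[c], m2.variances[c], atol=1e-12)

    def test_zero_variance_feature_stays_finite(self):
        X = np.array([[1.0, 5.0], [1.0, 6.0], [1.0, -5.0], [1.0, -6.0]])
        y = np.array([ADENO, ADENO, MESO, MESO])
        model = nbc_fit(X, y, smoothing=0.01)
        lp = nbc_log_posterior(model, X)
        assert np.all(np.isfinite(lp))


class TestTreePrimitives:
    def test_pure_node_has_zero_gini(self):
        assert gini([10, 0]) == 0.0

    def test_even_binary_node_has_half_gini(self):
        assert gini([5, 5]) == pytest.approx(0.5)

    def test_info_gain_matches_hand_entropy_bookkeeping(self):
        # parent 6/4 split into (4/0) and (2/4): hand-computed gain
        parent = [6, 4]
        parts = [[4, 0], [2, 4]]
        h = lambda p: -sum(q * np.log2(q) for q in p if q > 0)
        expected = h([0.6, 0.4]) - 0.4 * h([1.0]) - 0.6 * h([2 / 6, 4 / 6])
        assert info_gain(parent, parts) == pytest.approx(expected, abs=1e-12)

    def test_empty_node_rejected(self):
        with pytest.raises(InputError):
            gini([0, 0])

    def test_majority_vote_of_three_stumps(self):
        assert majority_vote([ADENO, ADENO, MESO]) == ADENO
        assert majority_vote([MESO, MESO, ADENO]) == MESO
        assert majority_vote([ADENO, MESO]) == ADENO  # tie toward the majority class

    def test_rbf_kernel_is_one_at_zero_distance(self, rng):
        x = rng.standard_normal(5)
        assert rbf_kernel(x, x, gamma=100.0) == 1.0
        assert 0 < rbf_kernel(x, x + 1.0, gamma=0.1) < 1


class TestSvm:
    def test_separable_set_fit_with_margin_contract(self, rng):
        X, y = _two_gaussians(rng, n=30, sep=3.0)
        cfg = RunConfig(svm_linear_c=10.0, svm_linear_class_weight=0.5)
        model = fit_classifier("SVM_linear", X, y, cfg)
        assert np.mean(model.predict(X) == y) == 1.0
        svc = model._impl
        margins = y_signed = np.where(y == svc.classes_[1], 1, -1)
        df = svc.decision_function(X)
        sv = svc.support_
        assert np.all(margins[sv] * df[sv] >= 1 - 1e-6)


class TestUnifiedContract:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_deterministic_and_order_invariant_scores(self, kind, rng):
        X, y = _two_gaussians(rng, n=24, sep=2.5)
        cfg = RunConfig(seed=9, svm_rbf_gamma=0.1, bldc_ridge=0.1)
        m1 = fit_classifier(kind, X, y, cfg, seed=9)
        m2 = fit_classifier(kind, X, y, cfg, seed=9)
        probe = rng.standard_normal((8, 2))
        np.testing.assert_allclose(m1.score_continuous(probe),
                                   m2.score_continuous(probe), atol=1e-12)
        if kind in ("BLDC", "NBC", "SVM_linear"):
            perm = np.random.default_rng(1).permutation(len(y))
            m3 = fit_classifier(kind, X[perm], y[perm], cfg, seed=9)
            np.testing.assert_allclose(m1.score_continuous(probe),
                                       m3.score_continuous(probe), atol=1e-8)

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_scores_live_on_the_target_interval(self, kind, rng):
        X, y = _two_gaussians(rng, n=24)
        cfg = RunConfig(svm_rbf_gamma=0.1, bldc_ridge=0.1)
        model = fit_classifier(kind, X, y, cfg)
        s = model.score_continuous(X)
        assert np.all(s >= cfg.t_meso - 1e-9) and np.all(s <= cfg.t_adeno + 1e-9)

    @pytest.mark.parametrize("kind", ["BLDC", "NBC"])
    def test_log_domain_survives_large_scaling(self, kind, rng):
        X, y = _two_gaussians(rng, n=24)
        cfg = RunConfig(bldc_ridge=0.1)
        model = fit_classifier(kind, X * 1e6, y, cfg)
        s = model.score_continuous(X * 1e6)
        assert np.all(np.isfinite(s))

    def test_single_class_training_set_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(FitError):
            fit_classifier("DTC", X, np.array([ADENO] * 10), RunConfig())

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_separable_regime_exceeds_95_percent_cv_accuracy(self, kind, small_matrix):
        """Smoke-level sanity on strongly separated synthetic data, with
        hyperparameters matched to the feature scale."""
        from mgx.pipeline import run_pipeline

        cfg = RunConfig(dr_method="DFA", classifier=kind, target_dim=100,
                        folds=10, seed=5, bldc_ridge=1.0, svm_rbf_gamma=1e-8)
        record, _, _ = run_pipeline(cfg, small_matrix)
        assert record.acc > 95.0, f"{kind} reached only {record.acc:.2f}%"
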