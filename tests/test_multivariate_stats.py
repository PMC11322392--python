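import numpy as np
import pytest

from dorsitrack.multivariate_stats import (crossvalidate_jackknife, fit_opls_da,
                                           fit_pca, preprocess,
                                           stratified_folds)


def two_class_data(rng, n_per=34, p=10, delta=None, noise=1.0):
    labels = np.array(["WAD"] * n_per + ["control"] * n_per)
    X = rng.normal(0, noise, (2 * n_per, p))
    if delta is not None:
        X[:n_per] += delta
    return X, labels


class TestPreprocess:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 2, (20, 6))
        Z, pp = preprocess(X)
        assert np.allclose(pp.inverse(Z), X, atol=1e-10)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (50, 4))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Z, _ = preprocess(X)
        assert np.allclose(Z, X, atol=1e-12)

    def test_constant_column_dropped(self, caplog):
        import logging
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        with caplog.at_level(logging.WARNING):
            Z, pp = preprocess(X)
        assert Z.shape[1] == 2
        assert list(pp.kept) == [0, 2]
        assert "zero-variance" in caplog.text

    def test_missing_values_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            preprocess(X)


class TestPca:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(3)
        X = np.outer(rng.normal(size=30), rng.normal(size=5))
        model = fit_pca(X, n_components=2, scale=False)
        assert model.explained_variance_fraction[0] > 0.999

    def test_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 6))
        model = fit_pca(X, n_components=6)
        Z, _ = preprocess(X)
        assert np.allclose(model.reconstruct(), Z, atol=1e-8)
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(6),
                           atol=1e-10)
        resid = Z - model.scores[:, :2] @ model.loadings[:, :2].T
        assert np.allclose(resid @ model.loadings[:, :2], 0, atol=1e-8)

    def test_isotropic_noise_flat_spectrum(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4000, 5))
        model = fit_pca(X, n_components=5)
        assert np.all(np.diff(model.explained_variance_fraction) <= 1e-12)
        assert model.explained_variance_fraction[0] < 0.25

    def test_deterministic_sign(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 4))
        a = fit_pca(X, 3)
        b = fit_pca(X.copy(), 3)
        assert np.array_equal(a.loadings, b.loadings)
        for j in range(3):
            assert a.loadings[np.abs(a.loadings[:, j]).argmax(), j] > 0


class TestOplsDa:
    def test_planted_variable_dominates_loading(self):
        rng = np.random.default_rng(7)
        X, labels = two_class_data(rng, n_per=20, p=8, noise=0.3)
        X[:20, 3] += 4.0
        model = fit_opls_da(X, labels, n_orthogonal=1)
        load = np.abs(model.predictive_loadings)
        assert load.argmax() == 3
        assert load[3] > 2 * np.sort(load)[-2]

    def test_score_orthogonality(self):
        rng = np.random.default_rng(8)
        X, labels = two_class_data(rng, n_per=15, p=12, delta=0.5)
        model = fit_opls_da(X, labels, n_orthogonal=2)
        for j in range(model.n_orthogonal):
            assert abs(model.scores @ model.ortho_scores[:, j]) < 1e-8

    def test_zero_orthogonal_equals_pls(self):
        """With no orthogonal components the model is a plain 1-component
        PLS-DA (independent NIPALS-style computation)."""
        rng = np.random.default_rng(9)
        X, labels = two_class_data(rng, n_per=10, p=6, delta=1.0)
        model = fit_opls_da(X, labels, n_orthogonal=0)
        Z, _ = preprocess(X)
        y = np.where(labels == "control", 1.0, -1.0)
        yc = y - y.mean()
        w_ref = Z.T @ yc
        w_ref /= np.linalg.norm(w_ref)
        t_ref = Z @ w_ref
        assert np.allclose(np.abs(model.scores), np.abs(t_ref), atol=1e-10)

    def test_prediction_separates_classes(self):
        rng = np.random.default_rng(10)
        X, labels = two_class_data(rng, n_per=20, p=5, delta=3.0, noise=0.5)
        model = fit_opls_da(X, labels)
        assert np.mean(model.predict(X) == labels) == 1.0

    def test_single_class_rejected(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="2 classes"):
            fit_opls_da(X, ["A"] * 10)


class TestFolds:
    def test_study_sized_partition(self):
        labels = np.array(["WAD"] * 34 + ["control"] * 34)
        folds = stratified_folds(labels, n_folds=7, seed=0)
        sizes = np.bincount(folds)
        assert sizes.sum() == 68
        assert set(sizes) <= {9, 10}  # p = one seventh of the subjects
        # every subject held out exactly once, stratification balanced
        for f in range(7):
            held = labels[folds == f]
            assert abs((held == "WAD").sum() - (held == "control").sum()) <= 2

    def test_deterministic_for_seed(self):
        labels = np.array(["a"] * 20 + ["b"] * 15)
        assert np.array_equal(stratified_folds(labels, seed=5),
                              stratified_folds(labels, seed=5))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            stratified_folds(["a", "b", "a"], n_folds=7)


class TestJackknife:
    def test_planted_signal_always_significant(self):
        """A strong noiseless class separator is flagged significant for
        every seed; pure-noise variables mostly are not."""
        rng = np.random.default_rng(12)
        flags_signal, noise_incl = [], []
        for rep in range(10):
            X, labels = two_class_data(rng, n_per=17, p=10, noise=1.0)
            X[:17, 0] += 8.0  # near-zero overlap separator
            model = crossvalidate_jackknife(X, labels, seed=rep)
            flags_signal.append(bool(model.significant[0]))
            noise_incl.append(np.mean(~model.significant[1:]))
        assert all(flags_signal)
        assert np.mean(noise_incl) >= 0.9

    def test_cv_accuracy_null_near_chance(self):
        rng = np.random.default_rng(13)
        accs = []
        for rep in range(20):
            X, labels = two_class_data(rng, n_per=14, p=8)
            labels = rng.permutation(labels)
            model = crossvalidate_jackknife(X, labels, seed=rep)
            accs.append(model.cv_accuracy)
        assert 0.3 < np.mean(accs) < 0.7

    def test_determinism(self):
        rng = np.random.default_rng(14)
        X, labels = two_class_data(rng, n_per=10, p=6, delta=1.0)
        a = crossvalidate_jackknife(X, labels, seed=3)
        b = crossvalidate_jackknife(X, labels, seed=3)
        assert np.array_equal(a.folds, b.folds)
        assert np.array_equal(a.ci_low, b.ci_low)
        assert np.array_equal(a.significant, b.significant)

    def test_ci_flag_consistency(self):
        rng = np.random.default_rng(15)
        X, labels = two_class_data(rng, n_per=12, p=7, delta=0.8)
        model = crossvalidate_jackknife(X, labels, seed=1)
        excludes = (model.ci_low > 0) | (model.ci_high < 0)
        assert np.array_equal(model.significant, excludes)
        assert np.all(model.ci_low <= model.predictive_loadings)
        assert np.all(model.ci_high >= model.predictive_loadings)
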