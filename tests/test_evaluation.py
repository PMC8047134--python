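"""CSP, classifier and validation-protocol tests.

The CSP solver is cross-checked against an independent brute-force route:
whiten by the inverse square root of the composite covariance, then take the
ordinary symmetric eigendecomposition of the whitened class-1 covariance.
"""

import numpy as np
import pytest
import scipy.linalg

import snnaug as sa
from snnaug.evaluation import spectral_logpower_features


def _epochs_with_exact_covariances(s1, s2, n_samples=64, seed=0):
    """One trial per class whose E E' equals n_samples * sigma exactly."""
    rng = np.random.default_rng(seed)
    c = s1.shape[0]
    trials = []
    for s in (s1, s2):
        q, _ = np.linalg.qr(rng.standard_normal((n_samples, n_samples)))
        root = scipy.linalg.sqrtm(s).real
        trials.append(root @ (np.sqrt(n_samples) * q[:, :c].T))
    data = np.stack(trials)
    return sa.EpochSet(data, np.array([0, 1]), 250.0,
                       [f"ch{i}" for i in range(c)], ["c1", "c2"])


def _random_spd(rng, c):
    a = rng.standard_normal((c, c))
    return a @ a.T + c * np.eye(c) * 0.1


def _bruteforce_csp(s1, s2, n_components):
    """Whitening-route generalized eigendecomposition oracle."""
    total = s1 + s2
    w, V = np.linalg.eigh(total)
    p = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    lam, U = np.linalg.eigh(p @ s1 @ p)
    order = np.argsort(lam)[::-1]
    filters = (U[:, order].T @ p)
    half = n_components // 2
    return np.vstack([filters[:half], filters[-half:]])


class TestCspFit:
    def test_constraint_identity(self, mi_epochs):
        model = sa.csp_fit(mi_epochs)
        gram = model.W @ (model.sigma1 + model.sigma2) @ model.W.T
        assert np.abs(gram - np.eye(model.W.shape[0])).max() <= 1e-8

    def test_covariances_unit_trace_spd(self, mi_epochs):
        model = sa.csp_fit(mi_epochs)
        for s in (model.sigma1, model.sigma2):
            assert np.trace(s) == pytest.approx(1.0)
            np.testing.assert_allclose(s, s.T, atol=1e-15)
            assert np.linalg.eigvalsh(s).min() >= -1e-12

    def test_identical_class_statistics_give_half_eigenvalues(self):
        rng = np.random.default_rng(3)
        s = _random_spd(rng, 4)
        epochs = _epochs_with_exact_covariances(s, s)
        model = sa.csp_fit(epochs, n_components=4)
        lam = np.diag(model.W @ model.sigma1 @ model.W.T)
        np.testing.assert_allclose(lam, 0.5, atol=1e-10)

    def test_axis_aligned_variance_recovers_channel_filter(self):
        s1 = np.diag([10.0, 1.0])
        s2 = np.diag([1.0, 10.0])
        epochs = _epochs_with_exact_covariances(s1, s2)
        model = sa.csp_fit(epochs, n_components=2)
        top = model.W[0] / np.linalg.norm(model.W[0])
        assert abs(top @ np.array([1.0, 0.0])) >= 0.99

    def test_matches_bruteforce_oracle_on_random_spd_pairs(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            c = int(rng.integers(4, 9))
            s1, s2 = _random_spd(rng, c), _random_spd(rng, c)
            epochs = _epochs_with_exact_covariances(s1, s2, seed=trial)
            model = sa.csp_fit(epochs, n_components=4)
            oracle = _bruteforce_csp(model.sigma1, model.sigma2, 4)
            angles = scipy.linalg.subspace_angles(model.W.T, oracle.T)
            assert angles.max() < 1e-6

    def test_requires_two_classes_and_two_channels(self, ssvep_epochs):
        with pytest.raises(ValueError, match="channels"):
            sa.csp_fit(ssvep_epochs)


class TestCspFeatures:
    def test_zero_trial_floored_not_nan(self, mi_epochs):
        model = sa.csp_fit(mi_epochs)
        zero = sa.EpochSet(np.zeros((2, 2, 50)), np.array([0, 1]), 250.0,
                           ["C3", "C4"], ["LH-MI", "RH-MI"])
        feats = sa.csp_features(model, zero)
        assert np.isfinite(feats).all()

    def test_scaling_shifts_log_variance_by_log4(self, mi_epochs):
        model = sa.csp_fit(mi_epochs)
        doubled = sa.EpochSet(2.0 * mi_epochs.data, mi_epochs.labels, mi_epochs.fs,
                              mi_epochs.channel_names, mi_epochs.class_names)
        np.testing.assert_allclose(
            sa.csp_features(model, doubled) - sa.csp_features(model, mi_epochs),
            np.log(4.0),
            atol=1e-10,
        )

    def test_features_linearly_separable_on_fixture(self, mi_epochs):
        model = sa.csp_fit(mi_epochs)
        feats = sa.csp_features(model, mi_epochs)
        clf = sa.fit_classifier(feats, mi_epochs.labels, "LDA")
        assert (clf.predict(feats) == mi_epochs.labels).mean() >= 0.9


class TestFitClassifier:
    def _separable(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        x = np.vstack([rng.normal(-3, 0.5, (n, 2)), rng.normal(3, 0.5, (n, 2))])
        y = np.repeat([0, 1], n)
        return x, y

    @pytest.mark.parametrize("kind", ["LDA", "SVM_linear"])
    def test_linear_separable_training_accuracy(self, kind):
        x, y = self._separable()
        clf = sa.fit_classifier(x, y, kind)
        assert (clf.predict(x) == y).all()

    def test_knn_k_lowered_on_tiny_sets(self, caplog):
        x = np.array([[0.0, 0], [0, 1], [5, 5], [5, 6]])
        y = np.array([0, 0, 1, 1])
        clf = sa.fit_classifier(x, y, "KNN5")
        assert clf.n_neighbors == 3  # lowered below n and kept odd
        assert clf.predict(np.array([[5.0, 5.5]]))[0] == 1

    def test_gaussian_classifier_near_bayes_on_known_blobs(self):
        """QDA on equal-covariance Gaussians: accuracy >= Bayes - 5%.

        Means +-1.5 on the first axis with unit spherical covariance give
        Bayes accuracy Phi(1.5) ~= 0.9332.
        """
        rng = np.random.default_rng(11)
        x_train = np.vstack([rng.normal((-1.5, 0), 1.0, (200, 2)),
                             rng.normal((1.5, 0), 1.0, (200, 2))])
        y_train = np.repeat([0, 1], 200)
        clf = sa.fit_classifier(x_train, y_train, "Gaussian")
        x_test = np.vstack([rng.normal((-1.5, 0), 1.0, (500, 2)),
                            rng.normal((1.5, 0), 1.0, (500, 2))])
        y_test = np.repeat([0, 1], 500)
        from scipy.stats import norm

        bayes = norm.cdf(1.5)
        assert (clf.predict(x_test) == y_test).mean() >= bayes - 0.05

    def test_naive_bayes_variant_available(self):
        x, y = self._separable()
        clf = sa.fit_classifier(x, y, "Gaussian", gaussian_variant="naive_bayes")
        assert (clf.predict(x) == y).mean() == 1.0

    def test_unknown_kind_rejected(self):
        x, y = self._separable()
        with pytest.raises(ValueError, match="unknown classifier"):
            sa.fit_classifier(x, y, "MLP")

    def test_lda_exposes_posteriors(self):
        x, y = self._separable()
        proba = sa.fit_classifier(x, y, "LDA").predict_proba(x)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)


class TestValidateCross:
    def test_identical_sets_equal_resubstitution(self, mi_epochs):
        copy = sa.EpochSet(mi_epochs.data.copy(), mi_epochs.labels.copy(),
                           mi_epochs.fs, mi_epochs.channel_names,
                           mi_epochs.class_names)
        report = sa.validate_cross(mi_epochs, copy, "a", "LDA")
        model = sa.csp_fit(mi_epochs)
        clf = sa.fit_classifier(sa.csp_features(model, mi_epochs),
                                mi_epochs.labels, "LDA")
        resub = (clf.predict(sa.csp_features(model, mi_epochs))
                 == mi_epochs.labels).mean()
        assert report.accuracy == pytest.approx(resub)

    def test_invariant_to_trial_order(self, mi_epochs, mi_mild_synth):
        rng = np.random.default_rng(4)
        shuffled = mi_mild_synth.subset(rng.permutation(mi_mild_synth.n_trials))
        a1 = sa.validate_cross(mi_epochs, mi_mild_synth, "a", "LDA").accuracy
        a2 = sa.validate_cross(mi_epochs, shuffled, "a", "LDA").accuracy
        assert a1 == pytest.approx(a2)

    def test_permuted_test_labels_fall_to_chance(self, mi_epochs, mi_mild_synth):
        rng = np.random.default_rng(5)
        chance = sa.EpochSet(mi_mild_synth.data,
                             rng.permutation(mi_mild_synth.labels),
                             mi_mild_synth.fs, mi_mild_synth.channel_names,
                             mi_mild_synth.class_names)
        acc = sa.validate_cross(mi_epochs, chance, "a", "LDA").accuracy
        # 99% binomial band around 0.5 for 200 test trials
        assert 0.5 - 2.576 * np.sqrt(0.25 / 200) <= acc <= 0.5 + 2.576 * np.sqrt(0.25 / 200)

    def test_class_mismatch_rejected(self, mi_epochs, ssvep_epochs):
        with pytest.raises(ValueError):
            sa.validate_cross(mi_epochs, ssvep_epochs, "a")


class TestBaselineCv:
    def test_split_arithmetic(self, mi_epochs):
        report = sa.baseline_cv(mi_epochs, n_folds=10, seed=0)
        assert report.n_train == 76 and report.n_test == 4
        assert len(report.fold_accuracies) == 10

    def test_separable_fixture_perfect(self, mi_epochs):
        assert sa.baseline_cv(mi_epochs, n_folds=10, seed=1).accuracy == 1.0

    def test_seed_reproducibility(self, mi_epochs):
        a = sa.baseline_cv(mi_epochs, n_folds=5, seed=3)
        b = sa.baseline_cv(mi_epochs, n_folds=5, seed=3)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_label_shuffled_data_near_chance(self):
        epochs = sa.make_mi_fixture(
            sa.FixtureSpec.mi(seed=21, erd_depth=0.0, n_trials_per_class=30)
        )
        report = sa.baseline_cv(epochs, n_folds=50, seed=2)
        # 99% band around 0.5, widened for fold correlation
        assert 0.32 <= report.accuracy <= 0.68

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(0)
        small = sa.EpochSet(rng.standard_normal((6, 2, 20)),
                            np.array([0, 0, 0, 1, 1, 1]), 250.0,
                            ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError, match="too few"):
            sa.baseline_cv(small, n_folds=2, test_fraction=0.05)


class TestWilcoxon:
    def test_uniform_shift_exact_p(self):
        a = np.arange(13.0)
        stat, p = sa.wilcoxon_signed_rank(a, a + 5.0)
        assert stat == 0.0
        assert p == pytest.approx(2.0 / 2**13)

    def test_identical_vectors_degenerate(self):
        a = np.arange(8.0)
        with pytest.raises(sa.DegenerateTestError):
            sa.wilcoxon_signed_rank(a, a.copy())

    def test_antisymmetric_differences_not_significant(self):
        a = np.zeros(10)
        d = np.array([1.0, -1, 2, -2, 3, -3, 4, -4, 5, -5])
        _, p = sa.wilcoxon_signed_rank(a + d, a)
        assert p > 0.5

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            sa.wilcoxon_signed_rank(np.array([1.0, 2, 3]), np.array([0.0, 0, 0]))


class TestSingleChannelFallback:
    def test_spectral_features_shape(self, ssvep_epochs):
        feats = spectral_logpower_features(ssvep_epochs)
        assert feats.shape[0] == ssvep_epochs.n_trials
        assert np.isfinite(feats).all()

    def test_ssvep_baseline_above_chance(self, ssvep_epochs):
        report = sa.baseline_cv(ssvep_epochs, n_folds=10, test_fraction=0.1, seed=0)
        assert report.accuracy >= 0.9
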