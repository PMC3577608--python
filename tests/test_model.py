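import numpy as np
import pytest

import connsig as cs
from connsig.model import (
    LabeledCohort,
    PCATransform,
    TrainedOvRModel,
    _confusion_percent,
    _fold_caches,
    fit_pca,
    loocv,
    permutation_test,
    train_model,
    train_ovr,
)
from sklearn.svm import SVC

CLASSES = cs.CLASS_ORDER


def three_cloud_cohort(n_per_class=10, sep=6.0, p=5, seed=0):
    """Well-separated Gaussian clouds, one per class."""
    rng = np.random.default_rng(seed)
    centers = {
        "patient": np.r_[sep, 0, np.zeros(p - 2)],
        "sibling": np.r_[0, sep, np.zeros(p - 2)],
        "control": np.r_[-sep, -sep, np.zeros(p - 2)],
    }
    feats, labels = [], []
    for cls in CLASSES:
        feats.append(centers[cls] + rng.standard_normal((n_per_class, p)))
        labels.extend([cls] * n_per_class)
    return np.vstack(feats), np.array(labels)


class TestFitPCA:
    def test_rank_one_data_recovers_line(self, rng):
        direction = np.array([3.0, -4.0, 12.0]) / 13.0
        t = rng.standard_normal(20)
        x = np.outer(t, direction) + np.array([1.0, 2.0, 3.0])
        pca = fit_pca(x, d=1)
        cosine = abs(pca.loadings[:, 0] @ direction)
        assert cosine == pytest.approx(1.0, abs=1e-10)
        z = pca.transform(x)[:, 0]
        recon = np.outer(z, pca.loadings[:, 0]) + pca.mean
        np.testing.assert_allclose(recon, x, atol=1e-10)

    def test_full_rank_reconstruction_exact(self, rng):
        x = rng.standard_normal((10, 50))
        pca = fit_pca(x)  # d = n - 1 by default
        centered = x - pca.mean
        recon = pca.transform(x) @ pca.loadings.T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_component_variances_match_eigendecomposition(self, rng):
        x = rng.standard_normal((10, 50))
        pca = fit_pca(x)
        # brute-force oracle: eigenvalues of the sample covariance
        cov = np.cov(x, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(pca.explained_variance, eig[: pca.d], atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        pca = fit_pca(rng.standard_normal((15, 40)))
        gram = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(gram, np.eye(pca.d), atol=1e-8)

    def test_d_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="d must be"):
            fit_pca(rng.standard_normal((10, 50)), d=10)

    def test_sign_convention_deterministic(self, rng):
        x = rng.standard_normal((12, 20))
        a, b = fit_pca(x), fit_pca(x.copy())
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for col in a.loadings.T:
            assert col[np.abs(col).argmax()] > 0


class TestTrainOvR:
    def test_separable_clouds_perfect_training_accuracy(self):
        x, y = three_cloud_cohort()
        model = train_model(x, y)
        assert np.all(model.predict(x) == y)

    def test_exactly_three_decision_functions(self):
        x, y = three_cloud_cohort()
        model = train_model(x, y)
        assert model.weights.shape[0] == 3
        assert model.biases.shape == (3,)

    def test_duplication_invariance_when_separable(self):
        x, y = three_cloud_cohort(sep=10.0)
        w1, b1 = train_ovr(x, y, cost_c=100.0)
        w2, b2 = train_ovr(
            np.vstack([x, x]), np.concatenate([y, y]), cost_c=100.0
        )
        np.testing.assert_allclose(w1, w2, atol=1e-6)
        np.testing.assert_allclose(b1, b2, atol=1e-6)

    def test_hard_margin_closed_form_1d(self):
        # support points at -1 and 1: gap 2, so |w| = 2 / gap = 1, b = 0
        z = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array(["patient", "patient", "sibling", "sibling"])
        w, b = train_ovr(z, y, cost_c=1e6, class_order=("patient", "sibling"))
        assert w[0, 0] == pytest.approx(-1.0, abs=1e-4)
        assert b[0] == pytest.approx(0.0, abs=1e-4)
        assert w[1, 0] == pytest.approx(1.0, abs=1e-4)

    def test_absent_class_rejected(self):
        x, y = three_cloud_cohort()
        with pytest.raises(ValueError, match="absent"):
            train_ovr(x[y != "control"], y[y != "control"])


class TestPredict:
    def test_deep_training_point_classified(self):
        x, y = three_cloud_cohort(sep=8.0)
        model = train_model(x, y)
        assert model.predict(x[:1])[0] == "patient"

    def test_tie_broken_by_class_order(self):
        pca = PCATransform(
            mean=np.zeros(2), loadings=np.eye(2), explained_variance=np.ones(2)
        )
        model = TrainedOvRModel(
            pca=pca,
            weights=np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 0.0]]),
            biases=np.zeros(3),
            class_order=CLASSES,
            cost_C=1.0,
        )
        # first two classifiers emit identical decision values
        assert model.predict(np.array([[2.0, 0.0]]))[0] == "patient"

    def test_dimension_mismatch_rejected(self):
        x, y = three_cloud_cohort()
        model = train_model(x, y)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.ones((1, 3)))

    def test_decision_values_match_backprojected_weights(self, rng):
        # projection identity: w . P(x) == (L w) . (x - mean)
        x, y = three_cloud_cohort(n_per_class=8, p=12, seed=3)
        model = train_model(x, y)
        back = model.pca.loadings @ model.weights.T  # p x k
        for _ in range(100):
            v = rng.standard_normal(12)
            via_pca = model.decision_values(v[None, :])[0]
            via_edges = (v - model.pca.mean) @ back + model.biases
            np.testing.assert_allclose(via_pca, via_edges, atol=1e-8)


class TestLOOCV:
    def test_one_hot_features_perfect(self):
        y = np.array(sum(([c] * 4 for c in CLASSES), []))
        x = np.zeros((12, 3))
        for i, cls in enumerate(y):
            x[i, CLASSES.index(cls)] = 1.0
        res = loocv(LabeledCohort(features=x, labels=y))
        assert res.accuracy == 1.0
        np.testing.assert_allclose(res.confusion_percent, np.eye(3) * 100)

    def test_identical_features_never_beat_majority_prior(self, rng):
        y = np.array(["patient"] * 6 + ["sibling"] * 4 + ["control"] * 4)
        x = np.ones((14, 5)) + 1e-9 * rng.standard_normal((14, 5))
        res = loocv(LabeledCohort(features=x, labels=y))
        assert res.accuracy <= 6 / 14 + 1e-12

    def test_single_subject_class_rejected(self):
        x, y = three_cloud_cohort(n_per_class=3)
        y = y.copy()
        y[y == "control"] = "sibling"
        y[0] = "control"
        with pytest.raises(ValueError, match="fewer than 2"):
            loocv(LabeledCohort(features=x, labels=y))

    def test_confusion_rows_sum_to_100(self, planted_cohort):
        rows = planted_cohort["cv"].confusion_percent.sum(axis=1)
        np.testing.assert_allclose(rows, 100.0, atol=1e-9)

    def test_fold_count_equals_subject_count(self, planted_cohort):
        cv = planted_cohort["cv"]
        assert cv.n_folds == planted_cohort["labeled"].n_subjects
        assert len(cv.fold_weights) == cv.n_folds
        assert len(cv.fold_pcas) == cv.n_folds

    def test_no_leakage_fold_model_ignores_held_out_subject(self, planted_cohort):
        # fold i's transform must equal a fresh fit on the data minus i
        cohort = planted_cohort["labeled"]
        cv = planted_cohort["cv"]
        for i in (0, cohort.n_subjects - 1):
            mask = np.ones(cohort.n_subjects, dtype=bool)
            mask[i] = False
            fresh = fit_pca(cohort.features[mask])
            np.testing.assert_array_equal(fresh.mean, cv.fold_pcas[i].mean)
            np.testing.assert_array_equal(fresh.loadings, cv.fold_pcas[i].loadings)

    def test_planted_cohort_classified_well(self, planted_cohort):
        assert planted_cohort["cv"].accuracy > 0.8


class TestConfusion:
    def test_brute_force_counts(self):
        t = np.array(["patient", "patient", "sibling", "control"])
        p = np.array(["patient", "sibling", "sibling", "patient"])
        conf = _confusion_percent(t, p, CLASSES)
        np.testing.assert_allclose(
            conf, [[50.0, 50.0, 0.0], [0.0, 100.0, 0.0], [100.0, 0.0, 0.0]]
        )


@pytest.fixture(scope="module")
def strong_cohort():
    y = np.array(sum(([c] * 5 for c in CLASSES), []))
    rng = np.random.default_rng(8)
    x = np.zeros((15, 4))
    for i, cls in enumerate(y):
        x[i, CLASSES.index(cls)] = 5.0
    x += 0.01 * rng.standard_normal(x.shape)
    return LabeledCohort(features=x, labels=y)


class TestPermutationTest:
    def test_observed_above_all_nulls_gives_add_one_p(self, strong_cohort):
        res = permutation_test(strong_cohort, n_perm=30, seed=2)
        assert res.observed_accuracy == 1.0
        assert np.all(res.null_accuracies < 1.0)
        assert res.p_value == pytest.approx(1 / 31)

    def test_p_value_formula_at_1000(self):
        # add-one estimator: obs above all 1000 nulls -> p = 1/1001 < 0.001
        assert (0 + 1) / (1000 + 1) == pytest.approx(0.000999, abs=1e-6)
        assert 1 / 1001 < 0.001

    def test_null_accuracies_in_unit_interval(self, strong_cohort):
        res = permutation_test(strong_cohort, n_perm=20, seed=3)
        assert np.all(res.null_accuracies >= 0)
        assert np.all(res.null_accuracies <= 1)
        assert 0 < res.p_value <= 1

    def test_seeded_reproducibility(self, strong_cohort):
        a = permutation_test(strong_cohort, n_perm=15, seed=11)
        b = permutation_test(strong_cohort, n_perm=15, seed=11)
        np.testing.assert_array_equal(a.null_accuracies, b.null_accuracies)

    def test_precomputed_kernel_route_matches_direct_svm(self, planted_cohort):
        # dual-route check: the cached-Gram path used inside the
        # permutation loop must reproduce the plain LOOCV predictions
        # when fed the unpermuted labels
        cohort = planted_cohort["labeled"]
        cv = planted_cohort["cv"]
        caches = _fold_caches(cohort.features, None)
        y = cohort.labels
        for i, (mask, gram, g_test) in enumerate(caches):
            decisions = []
            for cls in CLASSES:
                ybin = np.where(y[mask] == cls, 1, -1)
                clf = SVC(kernel="precomputed", C=1.0, shrinking=False)
                clf.fit(gram, ybin)
                decisions.append(
                    clf.dual_coef_[0] @ g_test[clf.support_] + clf.intercept_[0]
                )
            assert CLASSES[int(np.argmax(decisions))] == cv.predicted_labels[i]

    def test_invalid_n_perm_rejected(self, strong_cohort):
        with pytest.raises(ValueError):
            permutation_test(strong_cohort, n_perm=0)
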