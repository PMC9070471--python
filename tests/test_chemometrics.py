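"""PCA, PLS-DA, VIP refinement, ROC and classification metrics."""

import warnings

import numpy as np
import pytest

from aadkit import chemometrics as cm


def make_blobs(n_per_class=8, n_features=20, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, cls in enumerate(["A", "B", "C"]):
        centre = np.zeros(n_features)
        centre[k] = sep
        X.append(centre + rng.normal(size=(n_per_class, n_features)))
        y += [cls] * n_per_class
    return np.vstack(X), np.array(y)


class TestPCA:
    def test_collinear_data_one_component(self):
        x = np.linspace(0, 1, 10)
        table = np.column_stack([x, 2 * x])
        res = cm.pca(table, scale=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_scores_match_closed_form_on_tiny_design(self):
        # centred data [[1,1],[-1,-1],[0,0]]: PC1 along (1,1)/sqrt(2),
        # scores (sqrt(2), -sqrt(2), 0) -- eigendecomposition by hand
        X = np.array([[1.0, 1.0], [-1.0, -1.0], [0.0, 0.0]])
        res = cm.pca(X, center=True, scale=False)
        np.testing.assert_allclose(
            res.scores[:, 0], [np.sqrt(2), -np.sqrt(2), 0.0], atol=1e-12
        )
        np.testing.assert_allclose(np.abs(res.loadings[:, 0]), 1 / np.sqrt(2))

    def test_scaled_pca_invariant_to_units(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 4))
        res1 = cm.pca(X, scale=True)
        X2 = X.copy()
        X2[:, 0] *= 1000.0  # change of units
        res2 = cm.pca(X2, scale=True)
        np.testing.assert_allclose(res1.scores, res2.scores, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        res = cm.pca(rng.normal(size=(15, 5)))
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cm.pca(np.ones((1, 3)))


class TestPLSDA:
    def test_separable_classes_fit_perfectly(self):
        X = np.array([[0.0, 0], [0.1, 0], [5.0, 0], [5.1, 0]])
        y = np.array(["a", "a", "b", "b"])
        model = cm.fit_plsda(X, y, 1)
        assert (model.predict(X) == y).all()

    def test_duplicated_samples_leave_model_unchanged(self):
        X, y = make_blobs(n_per_class=5, seed=3)
        m1 = cm.fit_plsda(X, y, 2)
        m2 = cm.fit_plsda(np.vstack([X, X]), np.r_[y, y], 2)
        assert (m1.predict(X) == m2.predict(X)).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            cm.fit_plsda(np.random.default_rng(0).normal(size=(6, 3)), ["a"] * 6, 1)

    def test_excess_components_capped_with_warning(self):
        X, y = make_blobs(n_per_class=3, n_features=4, seed=4)
        with pytest.warns(UserWarning, match="capped"):
            model = cm.fit_plsda(X, y, 50)
        assert model.n_components <= X.shape[0] - 1

    def test_scores_orthogonal(self):
        X, y = make_blobs(seed=5)
        model = cm.fit_plsda(X, y, 4)
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_full_rank_pls_equals_least_squares_fit(self):
        # with as many components as the data rank, PLS reproduces the OLS
        # fitted values of Y on centred X (independent lstsq oracle)
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        y = np.array(["a"] * 5 + ["b"] * 5)
        model = cm.fit_plsda(X, y, 3)
        Y = np.column_stack([(y == "a").astype(float), (y == "b").astype(float)])
        Xc = np.column_stack([np.ones(10), X])
        beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
        np.testing.assert_allclose(model.decision_scores(X), Xc @ beta, atol=1e-8)


class TestVIP:
    @pytest.mark.parametrize("n_components", [1, 2, 4])
    def test_mean_squared_vip_is_one(self, n_components):
        X, y = make_blobs(seed=7)
        model = cm.fit_plsda(X, y, n_components)
        vip = cm.vip_scores(model)
        assert (vip >= 0).all()
        assert (vip**2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_dominant_variable_scores_above_one(self):
        rng = np.random.default_rng(8)
        n = 30
        signal = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = rng.normal(size=(n, 10)) * 0.1
        X[:, 0] += signal * 5
        y = np.where(signal > 0, "a", "b")
        model = cm.fit_plsda(X, y, 1)
        vip = cm.vip_scores(model)
        assert vip[0] > 1.0
        assert (vip[1:] < vip[0]).all()


class TestSelectNComponents:
    def test_single_factor_data_needs_one_component(self):
        rng = np.random.default_rng(9)
        n = 40
        t = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = np.outer(t * 6, np.ones(5)) + rng.normal(size=(n, 5)) * 0.2
        y = np.where(t > 0, "a", "b")
        assert cm.select_n_components(X, y, max_components=5, seed=0) == 1

    def test_deterministic_given_seed(self, spectrum_set):
        X = spectrum_set.X[:, :200]
        y = spectrum_set.tissue_type
        k1 = cm.select_n_components(X, y, max_components=5, seed=11)
        k2 = cm.select_n_components(X, y, max_components=5, seed=11)
        assert k1 == k2

    def test_singleton_class_stays_in_training(self):
        X, y = make_blobs(n_per_class=4, seed=10)
        y = y.astype(object)
        y[0] = "rare"
        with pytest.warns(UserWarning, match="rare"):
            k = cm.select_n_components(X, y, max_components=3, seed=0)
        assert 1 <= k <= 3


class TestRepeatedEvaluation:
    def test_same_seed_identical_summaries(self, spectrum_set):
        X = spectrum_set.X
        y = spectrum_set.tissue_type
        s1, v1 = cm.repeated_evaluation(X, y, n_repeats=5, seed=21)
        s2, v2 = cm.repeated_evaluation(X, y, n_repeats=5, seed=21)
        assert s1.per_repeat.equals(s2.per_repeat)
        np.testing.assert_array_equal(v1.per_repeat, v2.per_repeat)

    def test_singleton_class_cannot_be_stratified(self):
        X = np.random.default_rng(0).normal(size=(7, 4))
        y = np.array(["a", "a", "a", "b", "b", "b", "c"])
        with pytest.raises(ValueError, match="c"):
            cm.repeated_evaluation(X, y, n_repeats=2, seed=0)

    def test_metrics_bounded(self, spectrum_set):
        summary, _ = cm.repeated_evaluation(
            spectrum_set.X, spectrum_set.tissue_type, n_repeats=3, seed=2
        )
        vals = summary.per_repeat[["accuracy", "precision", "recall", "f1"]].to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()


class TestRefineByVIP:
    def test_uninformative_profile_rejected(self):
        profile = cm.VIPProfile(np.ones((5, 10)))
        with pytest.raises(ValueError, match="VIP"):
            cm.refine_by_vip(profile)

    def test_single_repeat_mean_equals_median(self):
        vip = np.array([[2.0, 0.5, 1.5]])
        profile = cm.VIPProfile(vip)
        np.testing.assert_array_equal(profile.mean, profile.median)
        np.testing.assert_array_equal(cm.refine_by_vip(profile), [True, False, True])

    def test_planted_markers_selected_on_default_cohort(self, spectrum_set):
        summary, vip = cm.repeated_evaluation(
            spectrum_set.X, spectrum_set.tissue_type, n_repeats=10, seed=5
        )
        selected = cm.refine_by_vip(vip)
        marker_bins = [
            b for bins in spectrum_set.class_marker_bins.values() for b in bins
        ]
        assert selected[marker_bins].all()


class TestROC:
    def test_perfect_separation(self):
        roc = cm.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_identical_scores_chance_level(self):
        roc = cm.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_hand_enumerated_rank_statistic(self):
        roc = cm.roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_curve_endpoints(self):
        roc = cm.roc_auc([0.7, 0.3, 0.6, 0.2], [1, 0, 0, 1])
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)

    def test_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        scores = rng.normal(size=50)
        truth = rng.integers(0, 2, 50)
        roc = cm.roc_auc(scores, truth)
        assert roc.auc == pytest.approx(roc_auc_score(truth, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cm.roc_auc([0.1, 0.2], [1, 1])


class TestClassificationMetrics:
    def test_diagonal_confusion_all_ones(self):
        m = cm.classification_metrics(np.diag([3, 4, 5]))
        assert m == {"accuracy": 1.0, "precision": 1.0, "recall": 1.0, "f1": 1.0}

    def test_hand_computed_three_class_accuracy(self):
        confusion = np.array([[2, 1, 0], [0, 3, 0], [1, 0, 3]])
        m = cm.classification_metrics(confusion)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_never_predicted_class_zero_precision(self):
        confusion = np.array([[0, 2], [0, 3]])
        m = cm.classification_metrics(confusion)
        assert m["precision"] == pytest.approx((0.0 + 3 / 5) / 2)

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            cm.classification_metrics(np.zeros((2, 2)))
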