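"""Classifier and cross-validation protocol contracts."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from ramancell.chemometrics import (
    LinearSVM, PCALDAClassifier, SmallTreeEnsemble, TreeClassifier,
    cross_validate, learning_curve, pca_fit)


def two_clouds(n=60, gap=8.0, dim=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n, dim))
    b = rng.normal(0, 1, (n, dim))
    b[:, 0] += gap
    X = np.vstack([a, b])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


def null_clouds(n=60, dim=5, seed=0):
    return two_clouds(n=n, gap=0.0, dim=dim, seed=seed)


class TestPCA:
    def test_rank_one_data_single_component(self, rng):
        v = rng.normal(size=20)
        X = np.outer(rng.normal(size=50), v)
        pca = pca_fit(X, n_components=3)
        assert pca.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_loadings_orthonormal_and_sign_fixed(self, rng):
        X = rng.normal(size=(100, 30))
        pca = pca_fit(X, n_components=10)
        G = pca.components_ @ pca.components_.T
        np.testing.assert_allclose(G, np.eye(10), atol=1e-8)
        for v in pca.components_:
            assert v[np.argmax(np.abs(v))] > 0
        evr = pca.explained_variance_ratio_
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-12

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(10, 5)), n_components=8)

    def test_best_pc_separates_default_classes(self, two_class_full):
        from scipy import stats
        _, res = two_class_full
        X, y = res.matrix, res.labels
        pca = pca_fit(X, n_components=10)
        T = pca.transform(X)
        pvals = [stats.ttest_ind(T[y == "SW480", k],
                                 T[y == "SW620", k]).pvalue
                 for k in range(10)]
        assert min(pvals) < 1e-6


class TestPCALDA:
    def test_separated_clouds_perfect_training(self):
        X, y = two_clouds()
        m = PCALDAClassifier(n_components=3).fit(X, y)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_five_classes_have_ten_discriminants(self, rng):
        X = rng.normal(size=(50, 8))
        y = np.repeat(list("ABCDE"), 10)
        m = PCALDAClassifier(n_components=4).fit(X, y)
        assert len(m.discriminants_) == 10

    def test_null_classes_at_chance(self):
        X, y = null_clouds(n=100)
        res = cross_validate(PCALDAClassifier(n_components=3), X, y,
                             k=5, reps=2, seed=0)
        assert abs(res.accuracy_mean - 50.0) <= 3 * res.accuracy_se + 5.0

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.array(["A", "A", "A", "A", "B"])
        with pytest.raises(ValueError):
            PCALDAClassifier(n_components=2).fit(X, y)


class TestTree:
    def test_threshold_data_depth_one(self):
        X = np.linspace(0, 1, 40).reshape(-1, 1)
        y = (X[:, 0] > 0.5).astype(int)
        m = TreeClassifier().fit(X, y)
        assert m.tree_.get_depth() == 1
        assert np.mean(m.predict(X) == y) == 1.0

    def test_xor_needs_depth_two(self, rng):
        # slightly unbalanced quadrants so the greedy first split has
        # positive Gini gain; any single split still caps at 75% by
        # exhaustive enumeration
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        sizes = [70, 30, 70, 30]
        X = np.vstack([np.tile(b, (s, 1))
                       for b, s in zip(base, sizes)])
        y = np.concatenate([np.full(s, lbl)
                            for s, lbl in zip(sizes, [0, 1, 1, 0])])
        deep = TreeClassifier(max_depth=2).fit(X, y)
        shallow = TreeClassifier(max_depth=1).fit(X, y)
        assert np.mean(deep.predict(X) == y) == 1.0
        assert np.mean(shallow.predict(X) == y) <= 0.75 + 1e-9

    def test_label_permutation_at_chance(self, two_class_small, rng):
        _, res = two_class_small
        y = rng.permutation(res.labels)
        cv = cross_validate(TreeClassifier(), res.matrix, y,
                            k=5, reps=2, seed=1)
        assert abs(cv.accuracy_mean - 50.0) <= 3 * cv.accuracy_se + 7.0

    def test_split_wavenumbers_reported(self, two_class_small):
        _, res = two_class_small
        m = TreeClassifier(wavenumbers=res.chemo_set.wavenumbers)
        m.fit(res.matrix, res.labels)
        assert m.split_wavenumbers_.size >= 1
        assert np.all((m.split_wavenumbers_ >= 730)
                      & (m.split_wavenumbers_ <= 3000))


class TestEnsemble:
    def test_separable_perfect_by_round_one(self):
        X, y = two_clouds()
        m = SmallTreeEnsemble(n_rounds=1).fit(X, y)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_single_round_matches_single_tree(self, rng):
        X = rng.normal(size=(80, 6))
        y = (X[:, 2] + 0.3 * X[:, 4] > 0).astype(int)
        ens = SmallTreeEnsemble(n_rounds=1, max_depth=2).fit(X, y)
        tree = TreeClassifier(max_depth=2).fit(X, y)
        assert np.array_equal(ens.predict(X), tree.predict(X))

    def test_frequent_wavenumbers_fall_in_contrast_bands(
            self, two_class_small):
        """The ensemble's most-chosen wavenumbers lie inside bands whose
        generator amplitudes differ between SW480 and SW620."""
        from ramancell.catalog import BAND_CATALOG, _CLASS_CONTRAST
        _, res = two_class_small
        wn = res.chemo_set.wavenumbers
        m = SmallTreeEnsemble(n_rounds=30, wavenumbers=wn, random_state=0)
        m.fit(res.matrix, res.labels)
        top = [w for w, _ in m.frequency_table_[:5]]
        informative = [b for b in BAND_CATALOG
                       if abs(np.log(_CLASS_CONTRAST[b.center][1]
                                     / _CLASS_CONTRAST[b.center][0])) > 0.05]
        for w in top:
            assert any(abs(w - b.center) <= 3 * b.width
                       for b in informative), w

    def test_invalid_rounds_rejected(self, rng):
        with pytest.raises(ValueError):
            SmallTreeEnsemble(n_rounds=0).fit(rng.normal(size=(10, 2)),
                                              [0, 1] * 5)


class TestSVM:
    def test_separated_clouds_perfect(self):
        X, y = two_clouds()
        m = LinearSVM().fit(X, y)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_null_at_chance(self):
        X, y = null_clouds(n=100)
        res = cross_validate(LinearSVM(), X, y, k=5, reps=2, seed=3)
        assert abs(res.accuracy_mean - 50.0) <= 3 * res.accuracy_se + 5.0


class _AlwaysRight(ClassifierMixin, BaseEstimator):
    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return (X[:, 0] > 0).astype(int)


class _CoinFlip(ClassifierMixin, BaseEstimator):
    def __init__(self, random_state=0):
        self.random_state = random_state

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        rng = np.random.default_rng(self.random_state)
        return rng.integers(0, 2, X.shape[0])


class TestCrossValidate:
    def test_oracle_classifier_scores_100(self, rng):
        X = rng.normal(size=(100, 3))
        y = (X[:, 0] > 0).astype(int)
        res = cross_validate(_AlwaysRight(), X, y, k=10, reps=5, seed=0)
        assert res.accuracy_mean == 100.0
        assert res.accuracy_se == 0.0

    def test_coin_flip_within_3se_of_chance(self, rng):
        X = rng.normal(size=(500, 2))
        y = rng.integers(0, 2, 500)
        res = cross_validate(_CoinFlip(), X, y, k=10, reps=5, seed=0)
        binom_se = 100 * 0.5 / np.sqrt(500 * 5)
        assert abs(res.accuracy_mean - 50.0) <= 3 * max(res.accuracy_se,
                                                        binom_se)

    def test_same_seed_identical(self, two_class_small):
        _, res = two_class_small
        a = cross_validate(PCALDAClassifier(), res.matrix, res.labels,
                           k=5, reps=2, seed=7)
        b = cross_validate(PCALDAClassifier(), res.matrix, res.labels,
                           k=5, reps=2, seed=7)
        assert a.per_fold == b.per_fold
        assert np.array_equal(a.confusion, b.confusion)

    def test_confusion_rows_sum_to_test_counts(self, two_class_small):
        _, res = two_class_small
        cv = cross_validate(PCALDAClassifier(), res.matrix, res.labels,
                            k=5, reps=2, seed=0)
        counts = {c: int(np.sum(res.labels == c)) for c in cv.classes}
        for i, c in enumerate(cv.classes):
            assert cv.confusion[i].sum() == counts[c] * 2  # 2 repetitions

    def test_fewer_samples_than_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_validate(_AlwaysRight(), rng.normal(size=(5, 2)),
                           np.array([0, 1, 0, 1, 0]), k=10)

    def test_leaky_variant_never_below_nested_on_null(self, two_class_small,
                                                      rng):
        """PCA computed on the full data can only flatter the accuracy;
        the default protocol must remain the nested one."""
        _, res = two_class_small
        y = rng.permutation(res.labels)
        nested = cross_validate(PCALDAClassifier(), res.matrix, y,
                                k=5, reps=2, seed=2)
        leaky = cross_validate(PCALDAClassifier(), res.matrix, y,
                               k=5, reps=2, seed=2, leaky_pca=True)
        tol = 3 * (nested.accuracy_se + leaky.accuracy_se)
        assert leaky.accuracy_mean >= nested.accuracy_mean - tol
        assert nested.protocol["leaky_pca"] is False


class TestLearningCurve:
    def test_separable_curve_saturates_at_100(self):
        X, y = two_clouds(n=120)
        out = learning_curve(PCALDAClassifier(n_components=3), X, y,
                             train_sizes=[10, 20, 40], test_n=40,
                             n_resamples=15, seed=0)
        assert out["accuracy_mean"][-1] > 99.0
        assert out["weibull"]["saturation"] <= 100.0

    def test_accuracy_nondecreasing_within_se(self, two_class_small):
        _, res = two_class_small
        out = learning_curve(PCALDAClassifier(n_components=10),
                             res.matrix, res.labels,
                             train_sizes=[8, 16, 32], test_n=20,
                             n_resamples=20, seed=1)
        acc, se = out["accuracy_mean"], out["accuracy_se"]
        for i in range(len(acc) - 1):
            assert acc[i + 1] >= acc[i] - 3 * (se[i] + se[i + 1])
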