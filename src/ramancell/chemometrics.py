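"""Classifier suite and evaluation protocol for spectral chemometrics.

Estimators follow the scikit-learn contract (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) so they compose with
sklearn model selection:

* :class:`PCALDAClassifier` -- mean-centred PCA (25 components by default)
  followed by pairwise Fisher linear discriminants combined by one-vs-one
  voting; for k classes the model holds C(k, 2) discriminants.
* :class:`TreeClassifier` -- a single CART tree on raw wavenumber
  intensities, reporting its split wavenumbers.
* :class:`SmallTreeEnsemble` -- boosted depth-limited trees with a
  per-wavenumber selection-frequency table.
* :class:`LinearSVM` -- soft-margin linear-kernel SVM (one-vs-one for k>2).

Evaluation is stratified 10-fold cross-validation with 5 repetitions; the
reported uncertainty is the standard error sigma/sqrt(N) over the N = 50
fold estimates.  All data-dependent fitting (PCA included) is nested inside
training folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["PCALDAClassifier", "TreeClassifier", "SmallTreeEnsemble",
           "LinearSVM", "CVResult", "cross_validate", "learning_curve",
           "pca_fit"]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-|weight| element of each PC is positive."""
    out = components.copy()
    for i, v in enumerate(out):
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            out[i] = -v
    return out


def pca_fit(matrix: np.ndarray, n_components: int = 25) -> PCA:
    """Mean-centred PCA with the package's sign convention applied."""
    X = np.asarray(matrix, float)
    if n_components > min(X.shape):
        raise ValueError("more components than the data's rank allows")
    pca = PCA(n_components=n_components, svd_solver="full").fit(X)
    flip = np.array([
        -1.0 if v[int(np.argmax(np.abs(v)))] < 0 else 1.0
        for v in pca.components_])
    pca.components_ = pca.components_ * flip[:, None]
    return pca


class PCALDAClassifier(ClassifierMixin, BaseEstimator):
    """PCA score truncation followed by one-vs-one Fisher discriminants.

    For each unordered class pair a Fisher linear discriminant is computed
    on the PC scores from the pooled within-class covariance
    (ridge-regularised when near singular); prediction is majority vote over
    the pairwise discriminants, ties broken by the largest summed margin.
    """

    def __init__(self, n_components: int = 25, ridge: float = 1e-6):
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        for k, c in enumerate(classes):
            if np.sum(y_idx == k) < 2:
                raise ValueError(f"class {c!r} has fewer than 2 samples")
        self.classes_ = classes
        n_comp = min(self.n_components, min(X.shape) - 1)
        self.pca_ = pca_fit(X, n_comp)
        T = self.pca_.transform(X)
        self.discriminants_ = {}
        for i, j in combinations(range(classes.size), 2):
            Ti, Tj = T[y_idx == i], T[y_idx == j]
            mi, mj = Ti.mean(axis=0), Tj.mean(axis=0)
            Sw = ((Ti - mi).T @ (Ti - mi) + (Tj - mj).T @ (Tj - mj)) \
                / (len(Ti) + len(Tj) - 2)
            Sw = Sw + self.ridge * np.trace(Sw) / Sw.shape[0] \
                * np.eye(Sw.shape[0])
            w = np.linalg.solve(Sw, mj - mi)
            thr = 0.5 * float(w @ (mi + mj))
            self.discriminants_[(i, j)] = (w, thr)
        return self

    def _pair_scores(self, X):
        T = self.pca_.transform(X)
        return {pair: T @ w - thr
                for pair, (w, thr) in self.discriminants_.items()}

    def decision_function(self, X):
        """Two-class only: signed distance along the single discriminant."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        if self.classes_.size != 2:
            raise ValueError("decision_function is defined for 2 classes")
        return self._pair_scores(X)[(0, 1)]

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        k = self.classes_.size
        scores = self._pair_scores(X)
        votes = np.zeros((X.shape[0], k))
        margin = np.zeros((X.shape[0], k))
        for (i, j), s in scores.items():
            votes[s < 0, i] += 1
            votes[s >= 0, j] += 1
            margin[:, i] += np.maximum(-s, 0)
            margin[:, j] += np.maximum(s, 0)
        # ties broken by the largest summed margin
        best = np.argmax(votes + margin / (1.0 + margin.max()), axis=1) \
            if margin.size else np.argmax(votes, axis=1)
        return self.classes_[best]


class TreeClassifier(ClassifierMixin, BaseEstimator):
    """Single CART binary tree (Gini splitting) on raw intensities."""

    def __init__(self, max_depth=None, random_state: int = 0,
                 wavenumbers=None):
        self.max_depth = max_depth
        self.random_state = random_state
        self.wavenumbers = wavenumbers

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.tree_ = DecisionTreeClassifier(
            criterion="gini", max_depth=self.max_depth,
            random_state=self.random_state).fit(X, y)
        self.classes_ = self.tree_.classes_
        feats = self.tree_.tree_.feature
        used = np.unique(feats[feats >= 0])
        if self.wavenumbers is not None:
            self.split_wavenumbers_ = np.asarray(self.wavenumbers)[used]
        else:
            self.split_wavenumbers_ = used.astype(float)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.tree_.predict(X)


class SmallTreeEnsemble(ClassifierMixin, BaseEstimator):
    """Boosted depth-limited trees with wavenumber selection frequencies.

    An AdaBoost-style ensemble of small CART trees (depth <= 2 by default):
    the rule-based small-tree booster's behaviour of interest here -- many
    weak trees, each choosing a handful of wavenumbers, with the frequently
    chosen wavenumbers reported as candidate marker bands.
    """

    def __init__(self, n_rounds: int = 50, max_depth: int = 2,
                 learning_rate: float = 1.0, random_state: int = 0,
                 wavenumbers=None):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.wavenumbers = wavenumbers

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        self.ensemble_ = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=self.max_depth),
            n_estimators=self.n_rounds, learning_rate=self.learning_rate,
            random_state=self.random_state).fit(X, y)
        self.classes_ = self.ensemble_.classes_
        counts = np.zeros(X.shape[1])
        for est in self.ensemble_.estimators_:
            feats = est.tree_.feature
            for f in feats[feats >= 0]:
                counts[f] += 1
        self.feature_counts_ = counts
        order = np.argsort(-counts)
        wn = np.asarray(self.wavenumbers) if self.wavenumbers is not None \
            else np.arange(X.shape[1], dtype=float)
        self.frequency_table_ = [
            (float(wn[i]), int(counts[i])) for i in order if counts[i] > 0]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.ensemble_.predict(X)


class LinearSVM(ClassifierMixin, BaseEstimator):
    """Soft-margin linear-kernel SVM (one-vs-one for more than 2 classes)."""

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.svm_ = SVC(kernel="linear", C=self.C,
                        decision_function_shape="ovo").fit(X, y)
        self.classes_ = self.svm_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.svm_.predict(X)


@dataclass
class CVResult:
    """Cross-validated accuracy with its standard error.

    ``accuracy_se`` is sigma/sqrt(N) over the N = k_folds * repetitions
    fold-level accuracy estimates; ``confusion`` accumulates test-set counts
    over all folds and repetitions.
    """

    accuracy_mean: float          # percent
    accuracy_se: float            # percent
    per_fold: list = field(default_factory=list)
    confusion: np.ndarray = None
    classes: list = field(default_factory=list)
    protocol: dict = field(default_factory=dict)

    def __str__(self) -> str:
        return (f"CV accuracy {self.accuracy_mean:.1f} +/- "
                f"{self.accuracy_se:.1f}% "
                f"({self.protocol.get('k_folds')}x"
                f"{self.protocol.get('repetitions')} folds)")


def cross_validate(model, X, y, k: int = 10, reps: int = 5, seed: int = 0,
                   leaky_pca: bool = False) -> CVResult:
    """Stratified k-fold cross-validation with re-randomised repetitions.

    Every data-dependent statistic (PCA included) is fitted inside the
    training folds.  ``leaky_pca=True`` reproduces the leaky variant in
    which the PCA basis of a :class:`PCALDAClassifier` is computed once on
    the full dataset -- useful only to quantify the leakage bias.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.shape[0] < k:
        raise ValueError("fewer samples than folds")
    classes = np.unique(y)
    accs, confusion = [], np.zeros((classes.size, classes.size), dtype=int)
    shared_pca = None
    if leaky_pca:
        if not isinstance(model, PCALDAClassifier):
            raise ValueError("leaky_pca applies to PCALDAClassifier only")
        shared_pca = pca_fit(X, min(model.n_components, min(X.shape) - 1))
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + 1000 * rep)
        for train, test in skf.split(X, y):
            est = clone(model)
            if hasattr(est, "random_state"):
                est.set_params(random_state=seed + rep)
            est.fit(X[train], y[train])
            if shared_pca is not None:
                # leaked basis: swap in the whole-data PCA, refit the LDs
                est.pca_ = shared_pca
                _refit_lds(est, shared_pca.transform(X[train]), y[train])
            pred = est.predict(X[test])
            accs.append(float(np.mean(pred == y[test])) * 100.0)
            confusion += confusion_matrix(y[test], pred, labels=classes)
    accs = np.array(accs)
    return CVResult(
        accuracy_mean=float(accs.mean()),
        accuracy_se=float(accs.std(ddof=1) / np.sqrt(accs.size)),
        per_fold=accs.tolist(), confusion=confusion,
        classes=classes.tolist(),
        protocol={"k_folds": k, "repetitions": reps, "stratified": True,
                  "seed": seed, "leaky_pca": leaky_pca})


def _refit_lds(est: PCALDAClassifier, T: np.ndarray, y: np.ndarray) -> None:
    classes, y_idx = np.unique(y, return_inverse=True)
    est.discriminants_ = {}
    for i, j in combinations(range(classes.size), 2):
        Ti, Tj = T[y_idx == i], T[y_idx == j]
        mi, mj = Ti.mean(axis=0), Tj.mean(axis=0)
        Sw = ((Ti - mi).T @ (Ti - mi) + (Tj - mj).T @ (Tj - mj)) \
            / (len(Ti) + len(Tj) - 2)
        Sw = Sw + est.ridge * np.trace(Sw) / Sw.shape[0] * np.eye(Sw.shape[0])
        w = np.linalg.solve(Sw, mj - mi)
        est.discriminants_[(i, j)] = (w, 0.5 * float(w @ (mi + mj)))


def _weibull(n, sat, scale, shape, floor):
    return sat - (sat - floor) * np.exp(-np.power(n / scale, shape))


def learning_curve(model, X, y, train_sizes, test_n: int = 50,
                   n_resamples: int = 100, seed: int = 0):
    """Accuracy vs training-set size with a saturating Weibull-sigmoid fit.

    For each size, ``n_resamples`` random stratified train/test splits are
    drawn (test group of ``test_n`` cells); returns a dict with per-size
    mean and standard error and the fitted saturation parameter (<= 100%).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    means, ses = [], []
    for n_train in train_sizes:
        accs = []
        for _ in range(n_resamples):
            train_idx = []
            for c in classes:
                idx = np.flatnonzero(y == c)
                take = max(2, int(round(n_train / classes.size)))
                train_idx.append(rng.choice(idx, size=min(take, idx.size - 2),
                                            replace=False))
            train_idx = np.concatenate(train_idx)
            rest = np.setdiff1d(np.arange(y.size), train_idx)
            test_idx = rng.choice(rest, size=min(test_n, rest.size),
                                  replace=False)
            est = clone(model).fit(X[train_idx], y[train_idx])
            accs.append(float(np.mean(est.predict(X[test_idx])
                                      == y[test_idx])) * 100.0)
        accs = np.array(accs)
        means.append(accs.mean())
        ses.append(accs.std(ddof=1) / np.sqrt(accs.size))
    means, ses = np.array(means), np.array(ses)
    sizes = np.asarray(train_sizes, float)
    try:
        popt, _ = curve_fit(
            _weibull, sizes, means,
            p0=[min(means.max() + 1, 100.0), max(sizes.mean(), 1.0), 1.0,
                max(means.min() - 1, 0.0)],
            bounds=([0, 1e-6, 0.1, 0], [100.0, 1e6, 10.0, 100.0]),
            maxfev=20000)
        saturation = float(popt[0])
        fit_params = {"saturation": saturation, "scale": float(popt[1]),
                      "shape": float(popt[2]), "floor": float(popt[3])}
    except RuntimeError:
        saturation = float(means[-1])
        fit_params = {"saturation": saturation, "scale": None,
                      "shape": None, "floor": None}
    return {"train_sizes": sizes.tolist(), "accuracy_mean": means.tolist(),
            "accuracy_se": ses.tolist(), "weibull": fit_params}
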