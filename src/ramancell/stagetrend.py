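"""PLSR trend analysis of colorectal adenocarcinoma stage.

Regresses the SNV spectra of the SW480 / HT29 / SW620 lines on their ordinal
Duke stage codes (B primary -> 1, C primary -> 2, C metastasis -> 3) with
partial least squares, then keeps only the components whose per-cell scores
increase significantly with stage: unpaired two-sample one-tailed t-tests on
both adjacent class pairs (stage 1 < 2 and 2 < 3), each at p < alpha.
Components are oriented so the mean score increases with the stage code.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

from .catalog import STAGE_CODING

__all__ = ["StageTrendPLSR", "plsr_fit", "select_stage_components",
           "stage_report"]


class StageTrendPLSR(BaseEstimator):
    """PLS regression of spectra on ordinal disease stage with the
    stage-monotonicity component selection test.

    Parameters
    ----------
    n_components : int
        Components extracted before selection (default 10).
    alpha : float
        Significance level of each one-tailed adjacent-pair t-test.
    coding : dict
        Class label -> integer stage code; defaults to the Duke coding
        {SW480: 1, HT29: 2, SW620: 3}.
    all_pairs : bool
        Test every ordered class pair instead of adjacent pairs only.

    Attributes (after ``fit``)
    --------------------------
    components_ : (n_components, n_wavenumbers) oriented weight vectors.
    scores_ : (n_cells, n_components) oriented per-cell scores.
    selected_ : indices of components passing the stage-trend test.
    pairwise_p_ : (n_components, n_pairs) one-tailed p-values.
    """

    def __init__(self, n_components: int = 10, alpha: float = 0.01,
                 coding: dict | None = None, all_pairs: bool = False,
                 cv_seed: int = 0):
        self.n_components = n_components
        self.alpha = alpha
        self.coding = coding
        self.all_pairs = all_pairs
        self.cv_seed = cv_seed

    def fit(self, X, labels):
        X = np.asarray(X, float)
        labels = np.asarray(labels)
        coding = self.coding or STAGE_CODING
        known = np.isin(labels, list(coding))
        if not known.all():
            raise ValueError(
                f"labels without a stage code: "
                f"{sorted(set(labels[~known]))}")
        y = np.array([coding[c] for c in labels], dtype=float)
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 distinct stage codes")
        order = sorted(set(labels), key=lambda c: coding[c])
        for c in order:
            if np.sum(labels == c) < 2:
                raise ValueError(f"class {c!r} has fewer than 2 cells")
        n_comp = min(self.n_components, min(X.shape) - 1)
        pls = PLSRegression(n_components=n_comp, scale=False)
        pls.fit(X, y)
        scores = pls.x_scores_.copy()
        weights = pls.x_weights_.T.copy()
        # orient: mean score increases with stage code
        for k in range(n_comp):
            if np.corrcoef(scores[:, k], y)[0, 1] < 0:
                scores[:, k] *= -1
                weights[k] *= -1
        self.pls_ = pls
        self.stage_order_ = order
        self.stage_codes_ = {c: coding[c] for c in order}
        self.labels_ = labels
        self.components_ = weights
        self.scores_ = scores
        # Selection is tested on cross-fitted scores: each half of the data
        # is scored by the PLS fitted on the other half (orientation fixed
        # on the training half).  In-sample scores are constructed to covary
        # with the stage code, so t-tests on them would not control the
        # type-I rate; held-out scores do.
        test_scores = self._cross_fitted_scores(X, y, labels, n_comp)
        self.pairwise_p_, self.selected_ = self._select(
            test_scores, labels, order)
        return self

    def _cross_fitted_scores(self, X, y, labels, n_comp) -> np.ndarray:
        counts = {c: int(np.sum(labels == c)) for c in set(labels)}
        if min(counts.values()) < 4:
            warnings.warn(
                "classes too small for cross-fitted selection; falling back "
                "to in-sample scores (anti-conservative)", stacklevel=2)
            return self.scores_
        from sklearn.model_selection import StratifiedKFold
        out = np.empty((X.shape[0], n_comp))
        skf = StratifiedKFold(n_splits=2, shuffle=True,
                              random_state=self.cv_seed)
        for train, test in skf.split(X, labels):
            pls = PLSRegression(n_components=n_comp, scale=False)
            pls.fit(X[train], y[train])
            s_train = pls.x_scores_
            s_test = pls.transform(X[test])
            for k in range(n_comp):
                c = np.corrcoef(s_train[:, k], y[train])[0, 1]
                if c < 0:
                    s_test[:, k] = -s_test[:, k]
            out[test] = s_test
        return out

    def _select(self, scores, labels, order):
        if self.all_pairs:
            pairs = [(a, b) for i, a in enumerate(order)
                     for b in order[i + 1:]]
        else:
            pairs = list(zip(order[:-1], order[1:]))
        pvals = np.ones((scores.shape[1], len(pairs)))
        for k in range(scores.shape[1]):
            for j, (lo, hi) in enumerate(pairs):
                res = stats.ttest_ind(scores[labels == hi, k],
                                      scores[labels == lo, k],
                                      equal_var=True, alternative="greater")
                pvals[k, j] = res.pvalue
        selected = [k for k in range(scores.shape[1])
                    if np.all(pvals[k] < self.alpha)]
        return pvals, selected

    def transform(self, X):
        check_is_fitted(self)
        scores = self.pls_.transform(np.asarray(X, float))
        # re-apply orientation
        ref = np.sign(np.sum(self.pls_.x_weights_.T * self.components_,
                             axis=1))
        return scores * ref

    def report(self) -> pd.DataFrame:
        """Per-class score summaries for every selected component."""
        check_is_fitted(self)
        if not self.selected_:
            warnings.warn("no component passed the stage-trend test",
                          stacklevel=2)
            return pd.DataFrame(
                columns=["component", "class", "stage", "n", "mean",
                         "median", "q1", "q3"])
        rows = []
        for k in self.selected_:
            for c in self.stage_order_:
                s = self.scores_[self.labels_ == c, k]
                rows.append({
                    "component": k, "class": c,
                    "stage": self.stage_codes_[c], "n": s.size,
                    "mean": s.mean(), "median": float(np.median(s)),
                    "q1": float(np.quantile(s, 0.25)),
                    "q3": float(np.quantile(s, 0.75))})
        return pd.DataFrame(rows)

    def scores_frame(self) -> pd.DataFrame:
        """All individual cell scores (bee-swarm data) for selected
        components."""
        check_is_fitted(self)
        rows = []
        for k in self.selected_:
            for label, s in zip(self.labels_, self.scores_[:, k]):
                rows.append({"component": k, "class": label,
                             "stage": self.stage_codes_[label],
                             "score": float(s)})
        return pd.DataFrame(rows)

    def weights_frame(self, wavenumbers) -> pd.DataFrame:
        check_is_fitted(self)
        df = pd.DataFrame(self.components_.T,
                          columns=[f"component_{k}"
                                   for k in range(self.components_.shape[0])])
        df.insert(0, "wavenumber", np.asarray(wavenumbers, float))
        return df


def plsr_fit(matrix, labels, n_components: int = 10,
             coding: dict | None = None, alpha: float = 0.01
             ) -> StageTrendPLSR:
    """Fit the stage-trend PLSR model (functional wrapper)."""
    return StageTrendPLSR(n_components=n_components, alpha=alpha,
                          coding=coding).fit(matrix, labels)


def select_stage_components(scores, labels, alpha: float = 0.01,
                            coding: dict | None = None,
                            all_pairs: bool = False):
    """Stage-trend test on precomputed component scores.

    A component is selected iff one-tailed two-sample t-tests show its mean
    score strictly increasing across both adjacent stage pairs at p < alpha.
    Returns ``(selected indices, p-value matrix)``.
    """
    coding = coding or STAGE_CODING
    labels = np.asarray(labels)
    order = sorted(set(labels), key=lambda c: coding[c])
    if len(order) < 3:
        raise ValueError("need at least 3 classes for the stage chain")
    for c in order:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 cells")
    model = StageTrendPLSR(alpha=alpha, coding=coding, all_pairs=all_pairs)
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[0] == labels.size and scores.ndim == 2:
        pass
    else:
        scores = scores.T
    pvals, selected = model._select(scores, labels, order)
    return selected, pvals


def stage_report(model: StageTrendPLSR, wavenumbers=None):
    """Score summaries, individual scores and component weights."""
    out = {"summary": model.report(), "scores": model.scores_frame()}
    if wavenumbers is not None:
        out["weights"] = model.weights_frame(wavenumbers)
    return out
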