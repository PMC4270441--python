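"""Cross-validated linear-SVM decoding of category labels.

Confirmatory counterpart to kernel analysis: a one-vs-all linear SVM is
trained on 80% of the images and tested on the held-out 20%, with the
penalty strength chosen by internal cross-validation on the training rows
only; the split is re-randomized (stratified, so chance stays exactly 1/C)
and mean +/- std test accuracy over splits is reported.  Chance for the
balanced 7-way task is 1/7 ~= 14.3%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import LinearSVC

from .data import FeatureMatrix

__all__ = ["DecodingResult", "svm_cv_accuracy", "SVMDecoder"]

DEFAULT_C_GRID = np.logspace(-4, 2, 7)


@dataclass
class DecodingResult:
    accuracies: np.ndarray          # per-split test accuracy
    n_splits: int
    train_fraction: float
    chance_level: float
    best_C: np.ndarray = field(default=None, repr=False)

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std(self) -> float:
        return float(self.accuracies.std())


def _make_svm(C_grid, inner_folds: int, seed: int) -> GridSearchCV:
    base = LinearSVC(dual=False, max_iter=5000)
    return GridSearchCV(base, {"C": list(C_grid)},
                        cv=StratifiedKFold(inner_folds, shuffle=True,
                                           random_state=seed),
                        n_jobs=None)


def svm_cv_accuracy(rep, labels: np.ndarray, n_splits: int = 10,
                    train_frac: float = 0.8, seed: int = 0,
                    C_grid=DEFAULT_C_GRID, inner_folds: int = 5,
                    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
                    ) -> DecodingResult:
    """Mean test accuracy of a linear SVM over stratified random splits.

    The penalty C is selected per split by stratified k-fold grid search on
    the training rows only (no test-set leakage).  Pass ``splits`` (pairs of
    train/test index arrays) to share identical split membership across
    representations; otherwise splits are generated from ``seed``.
    """
    X = rep.values if isinstance(rep, FeatureMatrix) else np.asarray(rep, dtype=float)
    labels = np.asarray(labels)
    if splits is None:
        sss = StratifiedShuffleSplit(n_splits=n_splits, train_size=train_frac,
                                     random_state=seed)
        splits = list(sss.split(X, labels))
    accs, best_C = [], []
    for train, test in splits:
        if set(np.unique(labels[train])) != set(np.unique(labels)):
            raise ValueError("a category is absent from a training split")
        search = _make_svm(C_grid, inner_folds, seed)
        search.fit(X[train], labels[train])
        accs.append(search.score(X[test], labels[test]))
        best_C.append(search.best_params_["C"])
    chance = 1.0 / np.unique(labels).size
    return DecodingResult(accuracies=np.array(accs), n_splits=len(splits),
                          train_fraction=train_frac, chance_level=chance,
                          best_C=np.array(best_C))


class SVMDecoder(BaseEstimator, ClassifierMixin):
    """Estimator interface to the decoding protocol.

    ``fit(X, y)`` runs the full cross-validated evaluation and additionally
    fits a final model (with internally selected C) on all rows so
    ``predict`` works.  Fitted attributes: ``result_`` (DecodingResult),
    ``accuracy_``, ``accuracy_std_``, ``chance_level_``.
    """

    def __init__(self, n_splits: int = 10, train_frac: float = 0.8,
                 inner_folds: int = 5, random_state: int = 0):
        self.n_splits = n_splits
        self.train_frac = train_frac
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        self.result_ = svm_cv_accuracy(X, y, n_splits=self.n_splits,
                                       train_frac=self.train_frac,
                                       seed=self.random_state,
                                       inner_folds=self.inner_folds)
        self.accuracy_ = self.result_.mean
        self.accuracy_std_ = self.result_.std
        self.chance_level_ = self.result_.chance_level
        Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        self._final = _make_svm(DEFAULT_C_GRID, self.inner_folds,
                                self.random_state).fit(Xv, y)
        self.classes_ = self._final.classes_
        return self

    def predict(self, X):
        Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        return self._final.predict(Xv)

    def score(self, X=None, y=None) -> float:
        if X is None:
            return self.accuracy_
        return float(np.mean(self.predict(X) == np.asarray(y)))
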