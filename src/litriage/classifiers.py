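"""Base learners: linear SVM, the 10-member ensemble, and a Naive Bayes baseline.

Every SVM classification task in the pipeline uses a leave-one-subset-out
ensemble: the training set is split into ``m`` disjoint label-stratified
subsets and ``m`` soft-margin linear SVMs are trained, each with one
subset withheld; a document's score is the arithmetic mean of the member
margins.  All members share one feature set selected on the full task
training data.

The multinomial Naive Bayes classifier is retained purely as the
historical baseline for the curatability decision.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LinearSVM",
    "SvmEnsemble",
    "MultinomialNBScorer",
    "train_linear_svm",
    "decision_score",
    "train_ensemble",
    "ensemble_score",
]


class LinearSVM(BaseEstimator, ClassifierMixin):
    """Soft-margin linear SVM exposing the raw margin w.x + b.

    Minimises (1/2)||w||^2 + C sum hinge(y (w.x + b)) via the exact dual
    (libsvm SMO); the bias is unregularised.  Labels may be any two
    values; ``classes_[1]`` is the positive class.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-4):
        self.C = C
        self.tol = tol

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"LinearSVM needs exactly two classes, got {self.classes_.size}"
            )
        self._svc = SVC(kernel="linear", C=self.C, tol=self.tol)
        self._svc.fit(X, y)
        self.coef_ = np.asarray(self._svc.coef_.todense()).ravel() \
            if sp.issparse(self._svc.coef_) else np.asarray(self._svc.coef_).ravel()
        self.intercept_ = float(self._svc.intercept_[0])
        return self

    @classmethod
    def from_weights(cls, coef, intercept: float, classes=(0, 1),
                     C: float = 1.0, tol: float = 1e-4) -> "LinearSVM":
        """Rebuild a fitted model from stored weights (bundle deserialisation)."""
        model = cls(C=C, tol=tol)
        model.coef_ = np.asarray(coef, dtype=float).ravel()
        model.intercept_ = float(intercept)
        model.classes_ = np.asarray(classes)
        return model

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = sp.csr_matrix(X) if not sp.issparse(X) else X
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"dimension mismatch: model has {self.coef_.shape[0]} features, "
                f"input has {X.shape[1]}"
            )
        return np.asarray(X @ self.coef_).ravel() + self.intercept_

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


class SvmEnsemble(BaseEstimator, ClassifierMixin):
    """Leave-one-subset-out ensemble of ``m`` linear SVMs.

    A seeded, label-stratified shuffle partitions the training set into
    ``m`` disjoint subsets; member ``i`` is trained on all data except
    subset ``i``.  The ensemble margin is the mean of the member margins.

    Requires at least ``m`` examples of each class so every member's
    training set retains both labels.
    """

    def __init__(self, m: int = 10, C: float = 1.0, tol: float = 1e-4,
                 random_state: int = 0):
        self.m = m
        self.C = C
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        if self.m < 2:
            raise ValueError(f"ensemble size m must be >= 2, got {self.m}")
        X = sp.csr_matrix(X) if not sp.issparse(X) else X
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("SvmEnsemble needs exactly two classes")
        counts = [(y == c).sum() for c in self.classes_]
        if min(counts) < self.m:
            raise ValueError(
                f"need at least m={self.m} examples of each class, got {counts}"
            )
        splitter = StratifiedKFold(
            n_splits=self.m, shuffle=True, random_state=self.random_state
        )
        self.subsets_ = [test for _, test in splitter.split(np.zeros(len(y)), y)]
        self.members_ = []
        for held_out in self.subsets_:
            keep = np.setdiff1d(np.arange(len(y)), held_out)
            member = LinearSVM(C=self.C, tol=self.tol).fit(X[keep], y[keep])
            self.members_.append(member)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        scores = np.stack([mem.decision_function(X) for mem in self.members_])
        return scores.mean(axis=0)

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


class MultinomialNBScorer(BaseEstimator, ClassifierMixin):
    """Multinomial Naive Bayes with Laplace smoothing, scored as log posterior odds."""

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(self, X, y):
        if self.alpha <= 0:
            raise ValueError(f"smoothing alpha must be > 0, got {self.alpha}")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("MultinomialNBScorer needs exactly two classes")
        self._nb = MultinomialNB(alpha=self.alpha).fit(X, y)
        return self

    def decision_function(self, X) -> np.ndarray:
        """log P(pos|d) - log P(neg|d); for an empty document, the log prior odds."""
        check_is_fitted(self, "_nb")
        jll = (sp.csr_matrix(X) if not sp.issparse(X) else X) @ self._nb.feature_log_prob_.T
        jll = np.asarray(jll) + self._nb.class_log_prior_
        return jll[:, 1] - jll[:, 0]

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# thin functional wrappers

def train_linear_svm(vectors, labels, C: float = 1.0, tol: float = 1e-4) -> LinearSVM:
    return LinearSVM(C=C, tol=tol).fit(vectors, labels)


def decision_score(model: LinearSVM, vector) -> float:
    return float(model.decision_function(np.atleast_2d(vector))[0])


def train_ensemble(vectors, labels, m: int = 10, C: float = 1.0,
                   seed: int = 0) -> SvmEnsemble:
    return SvmEnsemble(m=m, C=C, random_state=seed).fit(vectors, labels)


def ensemble_score(ensemble: SvmEnsemble, vector) -> float:
    return float(ensemble.decision_function(np.atleast_2d(vector))[0])
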