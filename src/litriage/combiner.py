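"""Cost matrices and the neural-network combiner for sibling-set decisions.

For one sibling set of ``n`` categories, each document has a score
profile: the ``n`` one-vs-rest SVM ensemble margins.  A small multilayer
perceptron (one hidden layer of ``floor(n/2)`` units by default) maps the
profile to a probability vector over the siblings.

Cost sensitivity enters twice, each switchable independently:

* training-time: documents are reweighted by the row sums of the cost
  matrix, so classes whose misclassification is expensive dominate the
  weighted cross-entropy loss;
* decision-time: the predicted category minimises the expected
  misclassification cost ``sum_i p_i C[i, j]`` over predicted columns
  ``j`` instead of maximising probability.

Two canonical matrices are provided.  The Level-1 priority matrix
penalises predicting a truly high-priority document into a low-priority
category (cost 5) far more than other mistakes (1 within the same
priority tier at high, 0.2 within low).  The Level-2/3 catch-all matrix
penalises predicting a specific document into an "Other"/"Various"
bucket (cost 5) while forgiving the reverse (0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .taxonomy import PriorityPartition

__all__ = [
    "CostMatrix",
    "uniform_cost_matrix",
    "build_priority_cost_matrix",
    "build_catchall_cost_matrix",
    "instance_weights",
    "min_expected_cost_decision",
    "CostSensitiveMLP",
    "train_mlp",
    "predict_probs",
]


@dataclass(frozen=True)
class CostMatrix:
    """Square true-by-predicted misclassification-cost table.

    Rows are the true category, columns the predicted one, both in the
    canonical sibling order given by ``categories``.
    """

    categories: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.categories)
        if m.shape != (n, n):
            raise ValueError(f"cost matrix must be {n}x{n}, got {m.shape}")
        if (m < 0).any():
            raise ValueError("cost matrix entries must be non-negative")
        if np.diag(m).any():
            raise ValueError("cost matrix diagonal must be zero")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.categories)

    def cost(self, true: str, predicted: str) -> float:
        i = self.categories.index(true)
        j = self.categories.index(predicted)
        return float(self.matrix[i, j])


def uniform_cost_matrix(categories) -> CostMatrix:
    """0/1 misclassification costs: every error counts the same."""
    cats = tuple(categories)
    m = 1.0 - np.eye(len(cats))
    return CostMatrix(cats, m)


def build_priority_cost_matrix(
    partition: PriorityPartition,
    categories=None,
    c_hh: float = 1.0,
    c_ll: float = 0.2,
    c_hl: float = 5.0,
    c_lh: float = 1.0,
) -> CostMatrix:
    """Priority-aware Level-1 cost matrix.

    ``c_hl`` (true high, predicted low) is the expensive error: such
    documents silently drop out of the curation queue.  ``c_hh`` is a
    high-to-other-high mix-up, ``c_ll`` low-to-other-low, and ``c_lh``
    low-to-high (merely wastes reviewer time).
    """
    for name, c in (("c_hh", c_hh), ("c_ll", c_ll), ("c_hl", c_hl), ("c_lh", c_lh)):
        if c < 0:
            raise ValueError(f"{name} must be non-negative, got {c}")
    cats = tuple(categories) if categories is not None else partition.high + partition.low
    n = len(cats)
    m = np.zeros((n, n))
    for i, true in enumerate(cats):
        for j, pred in enumerate(cats):
            if i == j:
                continue
            t, p = partition.priority_of(true), partition.priority_of(pred)
            m[i, j] = {("high", "high"): c_hh, ("low", "low"): c_ll,
                       ("high", "low"): c_hl, ("low", "high"): c_lh}[(t, p)]
    return CostMatrix(cats, m)


def build_catchall_cost_matrix(
    categories,
    catch_all: dict[str, bool],
    c_spec: float = 1.0,
    c_to_catchall: float = 5.0,
    c_from_catchall: float = 0.2,
) -> CostMatrix:
    """Cost matrix discouraging predictions into catch-all siblings.

    Misrouting a specific document into a catch-all bucket costs
    ``c_to_catchall``; the reverse costs ``c_from_catchall``; every other
    error costs ``c_spec``.  Two catch-all siblings confused with each
    other also cost ``c_from_catchall`` (both are already buckets).
    """
    cats = tuple(categories)
    if not any(catch_all.get(c, False) for c in cats):
        raise ValueError(
            "no sibling is flagged catch_all; use uniform_cost_matrix instead"
        )
    for name, c in (("c_spec", c_spec), ("c_to_catchall", c_to_catchall),
                    ("c_from_catchall", c_from_catchall)):
        if c < 0:
            raise ValueError(f"{name} must be non-negative, got {c}")
    n = len(cats)
    m = np.zeros((n, n))
    for i, true in enumerate(cats):
        for j, pred in enumerate(cats):
            if i == j:
                continue
            if catch_all.get(pred, False):
                m[i, j] = c_from_catchall if catch_all.get(true, False) else c_to_catchall
            elif catch_all.get(true, False):
                m[i, j] = c_from_catchall
            else:
                m[i, j] = c_spec
    return CostMatrix(cats, m)


def instance_weights(labels, cost_matrix: CostMatrix) -> np.ndarray:
    """Per-document training weights from cost-matrix row sums.

    A document of true class ``i`` receives weight ``rowsum_i / mean of
    row sums over classes``; with a uniform 0/1 matrix every weight is 1.
    Invariant to positive rescaling of the matrix.
    """
    row_sums = cost_matrix.matrix.sum(axis=1)
    if row_sums.sum() == 0:
        raise ValueError("all-zero cost matrix gives no training signal")
    scale = row_sums / row_sums.mean()
    index = {c: i for i, c in enumerate(cost_matrix.categories)}
    return np.array([scale[index[lab]] for lab in labels])


def min_expected_cost_decision(probs, cost_matrix: CostMatrix) -> int:
    """Index of the predicted column minimising expected cost.

    Ties resolve to the smallest canonical index.  With uniform 0/1
    costs this reduces to argmax probability.
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (cost_matrix.n,):
        raise ValueError(
            f"probability vector length {p.shape} does not match {cost_matrix.n} categories"
        )
    expected = p @ cost_matrix.matrix
    return int(np.argmin(expected))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -40, 40)))


class CostSensitiveMLP(BaseEstimator, ClassifierMixin):
    """One-hidden-layer perceptron combiner over sibling score profiles.

    Architecture: input (one unit per sibling ensemble score) -> sigmoid
    hidden layer of ``hidden_units`` units (default ``max(2, n//2)``) ->
    softmax output over the siblings.  Trained by full-batch gradient
    descent with momentum on the weighted cross-entropy; inputs are
    standardised internally.  Fully deterministic given ``random_state``.

    If ``cost_matrix`` is given, ``reweight`` applies row-sum instance
    weights during training and ``min_cost_decision`` replaces argmax by
    the minimum-expected-cost rule at prediction time.
    """

    def __init__(self, hidden_units: int | None = None, epochs: int = 500,
                 lr: float = 0.3, momentum: float = 0.2, random_state: int = 0,
                 cost_matrix: CostMatrix | None = None, reweight: bool = True,
                 min_cost_decision: bool = True):
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.lr = lr
        self.momentum = momentum
        self.random_state = random_state
        self.cost_matrix = cost_matrix
        self.reweight = reweight
        self.min_cost_decision = min_cost_decision

    # -- internals ---------------------------------------------------------
    def _forward(self, X):
        a1 = _sigmoid(X @ self.W1_ + self.b1_)
        return a1, _softmax(a1 @ self.W2_ + self.b2_)

    @staticmethod
    def loss_and_grads(params, X, Y, w):
        """Weighted cross-entropy and its gradients (static, for gradient checks)."""
        W1, b1, W2, b2 = params
        a1 = _sigmoid(X @ W1 + b1)
        p = _softmax(a1 @ W2 + b2)
        wn = w / w.sum()
        loss = float(-(wn * np.log((p * Y).sum(axis=1) + 1e-300)).sum())
        dz2 = (p - Y) * wn[:, None]
        gW2 = a1.T @ dz2
        gb2 = dz2.sum(axis=0)
        da1 = dz2 @ W2.T
        dz1 = da1 * a1 * (1 - a1)
        gW1 = X.T @ dz1
        gb1 = dz1.sum(axis=0)
        return loss, (gW1, gb1, gW2, gb2)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("score profiles must be finite")
        y = np.asarray(y)
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.cost_matrix is not None:
            self.classes_ = np.asarray(self.cost_matrix.categories)
            unknown = set(y) - set(self.classes_)
            if unknown:
                raise ValueError(f"labels outside cost-matrix categories: {unknown}")
        else:
            self.classes_ = np.unique(y)
        n_classes = len(self.classes_)
        if len(set(y)) < 2:
            raise ValueError("combiner training needs at least two classes present")
        h = self.hidden_units if self.hidden_units is not None else max(2, n_classes // 2)
        if h < 1:
            raise ValueError(f"hidden_units must be >= 1, got {h}")

        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (X - self.mean_) / self.scale_

        class_index = {c: i for i, c in enumerate(self.classes_)}
        Y = np.zeros((len(y), n_classes))
        Y[np.arange(len(y)), [class_index[c] for c in y]] = 1.0

        if sample_weight is None:
            if self.cost_matrix is not None and self.reweight:
                sample_weight = instance_weights(y, self.cost_matrix)
            else:
                sample_weight = np.ones(len(y))
        w = np.asarray(sample_weight, dtype=float)

        rng = np.random.default_rng(self.random_state)
        d = X.shape[1]
        W1 = rng.uniform(-0.5, 0.5, (d, h)) / np.sqrt(d)
        b1 = np.zeros(h)
        W2 = rng.uniform(-0.5, 0.5, (h, n_classes)) / np.sqrt(h)
        b2 = np.zeros(n_classes)
        vel = [np.zeros_like(p) for p in (W1, b1, W2, b2)]
        params = [W1, b1, W2, b2]
        for _ in range(self.epochs):
            loss, grads = self.loss_and_grads(params, Xs, Y, w)
            for p, v, g in zip(params, vel, grads):
                v *= self.momentum
                v -= self.lr * g
                p += v
        self.W1_, self.b1_, self.W2_, self.b2_ = params
        self.loss_ = loss
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "W1_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.W1_.shape[0]:
            raise ValueError(
                f"profile length {X.shape[1]} does not match input width {self.W1_.shape[0]}"
            )
        _, p = self._forward((X - self.mean_) / self.scale_)
        return p

    def predict(self, X):
        p = self.predict_proba(X)
        if self.cost_matrix is not None and self.min_cost_decision:
            idx = [min_expected_cost_decision(row, self.cost_matrix) for row in p]
        else:
            idx = p.argmax(axis=1)
        return self.classes_[np.asarray(idx)]


def train_mlp(profiles, labels, weights=None, hidden_units: int | None = None,
              seed: int = 0, epochs: int = 500, lr: float = 0.3,
              cost_matrix: CostMatrix | None = None) -> CostSensitiveMLP:
    mlp = CostSensitiveMLP(hidden_units=hidden_units, epochs=epochs, lr=lr,
                           random_state=seed, cost_matrix=cost_matrix)
    return mlp.fit(profiles, labels, sample_weight=weights)


def predict_probs(mlp: CostSensitiveMLP, profile) -> np.ndarray:
    return mlp.predict_proba(np.atleast_2d(profile))[0]
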