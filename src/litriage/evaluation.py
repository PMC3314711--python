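"""Evaluation machinery: ROC/AUC, confusion analytics, cross-validation,
flat-vs-hierarchical comparison and the paired t-test.

AUC is computed by the Mann-Whitney rank formulation (tied score pairs
count one half), which equals the trapezoidal area under the ROC curve.
Confusion-matrix analytics follow the biocuration reading: rows are the
human expert's category, columns the classifier's prediction, and the
priority breakdown tallies how many truly high-priority documents the
classifier would have silently dropped into low-priority categories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .classifiers import SvmEnsemble
from .combiner import CostMatrix, CostSensitiveMLP
from .features import TfidfIgVectorizer
from .taxonomy import PriorityPartition

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "roc_auc",
    "sensitivity_specificity",
    "accuracy_from_confusion",
    "priority_breakdown",
    "CVPlan",
    "kfold_plan",
    "crossval_score_profiles",
    "cross_validate",
    "compare_flat_vs_hierarchical",
    "paired_t_test",
]


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(scores, labels) -> ROCResult:
    """ROC points and AUC for binary labels (positive = larger label).

    AUC uses the rank (Mann-Whitney) formulation: the probability that a
    random positive outscores a random negative, ties counting half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("roc_auc needs both classes present")
    pos = y == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(pos.astype(int), scores)
    return ROCResult(fpr=fpr, tpr=tpr, auc=float(auc))


def sensitivity_specificity(tp: int, fn: int, fp: int, tn: int) -> tuple[float, float]:
    """(sensitivity, specificity) as fractions; zero margins are an error."""
    for name, v in (("tp", tp), ("fn", fn), ("fp", fp), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both a positive and a negative margin are required")
    return tp / (tp + fn), tn / (tn + fp)


def accuracy_from_confusion(matrix, applicable_mask=None) -> float:
    """Fraction of on-diagonal documents, optionally over applicable rows only.

    ``applicable_mask`` marks the true-category rows where the level
    applies (branches that skip a level are excluded, as in the
    benchmark bookkeeping).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    mask = np.ones(m.shape[0], dtype=bool) if applicable_mask is None \
        else np.asarray(applicable_mask, dtype=bool)
    total = m[mask].sum()
    if total == 0:
        raise ValueError("no documents in applicable rows")
    correct = np.diag(m)[mask].sum()
    return float(correct / total)


def priority_breakdown(matrix, categories, partition: PriorityPartition) -> dict:
    """Six-block priority tally of a true-by-predicted confusion matrix."""
    m = np.asarray(matrix, dtype=float)
    cats = list(categories)
    hi = np.array([partition.priority_of(c) == "high" for c in cats])
    diag = np.diag(np.diag(m))
    off = m - diag
    out = {
        "high_correct": float(np.diag(m)[hi].sum()),
        "high_pred_other_high": float(off[np.ix_(hi, hi)].sum()),
        "high_pred_low": float(m[np.ix_(hi, ~hi)].sum()),
        "low_pred_high": float(m[np.ix_(~hi, hi)].sum()),
        "low_correct": float(np.diag(m)[~hi].sum()),
        "low_pred_other_low": float(off[np.ix_(~hi, ~hi)].sum()),
    }
    n_high = m[hi].sum()
    n_low = m[~hi].sum()
    out["n_true_high"] = float(n_high)
    out["n_true_low"] = float(n_low)
    out["pct_correct_high"] = float(out["high_correct"] / n_high) if n_high else float("nan")
    out["pct_correct_low"] = float(out["low_correct"] / n_low) if n_low else float("nan")
    out["n_pred_high"] = float(m[:, hi].sum())
    out["n_pred_low"] = float(m[:, ~hi].sum())
    return out


@dataclass(frozen=True)
class CVPlan:
    """Stratified k-fold assignment of document indices."""

    folds: tuple[np.ndarray, ...]
    seed: int
    labels: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_test(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        n = sum(len(f) for f in self.folds)
        test = self.folds[i]
        train = np.setdiff1d(np.arange(n), test)
        return train, test


def kfold_plan(n: int, k: int, labels, seed: int = 0) -> CVPlan:
    """Label-stratified k-fold plan over ``n`` documents."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    y = np.asarray(labels)
    if len(y) != n:
        raise ValueError("labels length must equal n")

    _, counts = np.unique(y, return_counts=True)
    stratify = counts.min() >= k
    if not stratify:
        logger.warning("a class has fewer than k=%d members; folds not stratified", k)

    def plan_with(s):
        if stratify:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=s)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # under-populated classes warn; handled below
            return tuple(test for _, test in splitter.split(np.zeros(n), y))

    folds = plan_with(seed)
    classes = set(np.unique(y))
    for attempt, s in enumerate((seed, seed + 1)):
        if attempt:
            folds = plan_with(s)
        bad = [i for i, f in enumerate(folds)
               if set(np.unique(np.delete(y, f))) != classes]
        if not bad:
            return CVPlan(folds=folds, seed=s, labels=y)
        logger.warning("fold(s) %s missing a class in training; resampling", bad)
    raise ValueError("a class is absent from some training fold even after resampling")


def crossval_score_profiles(texts, labels, plan: CVPlan, categories=None,
                            k_features: int = 100, C: float = 1.0, m: int = 10,
                            min_df: int = 3, seed: int = 0) -> tuple[np.ndarray, tuple[str, ...]]:
    """Pooled out-of-fold one-vs-rest ensemble score profiles.

    For each fold, per-category vectorizers (feature selection on that
    fold's training documents only) and SVM ensembles are trained on the
    training split; held-out documents get one margin per category.
    """
    texts = list(texts)
    y = np.asarray(labels)
    cats = tuple(categories) if categories is not None else tuple(sorted(set(y)))
    profiles = np.zeros((len(texts), len(cats)))
    for i in range(plan.k):
        train, test = plan.train_test(i)
        train_texts = [texts[j] for j in train]
        test_texts = [texts[j] for j in test]
        for c_idx, cat in enumerate(cats):
            y_bin = (y[train] == cat).astype(int)
            vec = TfidfIgVectorizer(k=k_features, min_df=min_df).fit(train_texts, y_bin)
            Xtr = vec.transform(train_texts)
            ens = SvmEnsemble(m=m, C=C, random_state=seed + i).fit(Xtr, y_bin)
            profiles[test, c_idx] = ens.decision_function(vec.transform(test_texts))
    return profiles, cats


def cross_validate(texts, labels, plan: CVPlan, categories=None,
                   k_features: int = 100, C: float = 1.0, m: int = 10,
                   cost_matrix: CostMatrix | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Per-category AUC and combiner accuracy table from out-of-fold scores.

    Shaped like the published per-level performance tables: one row per
    category with its document count, one-vs-rest AUC, and the combiner's
    per-category prediction accuracy (out-of-fold at the profile level).
    """
    y = np.asarray(labels)
    profiles, cats = crossval_score_profiles(
        texts, y, plan, categories, k_features, C, m, seed=seed
    )
    # combiner accuracy: second-stage CV over the pooled profiles
    pred = np.empty(len(y), dtype=object)
    inner = kfold_plan(len(y), plan.k, y, seed=seed + 1)
    for i in range(inner.k):
        train, test = inner.train_test(i)
        mlp = CostSensitiveMLP(cost_matrix=cost_matrix, random_state=seed)
        mlp.fit(profiles[train], y[train])
        pred[test] = mlp.predict(profiles[test])
    rows = []
    for c_idx, cat in enumerate(cats):
        is_cat = y == cat
        rows.append({
            "category": cat,
            "n": int(is_cat.sum()),
            "auc": roc_auc(profiles[:, c_idx], is_cat.astype(int)).auc,
            "combiner_accuracy": float((pred[is_cat] == cat).mean()),
        })
    return pd.DataFrame(rows)


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Classical paired two-sided t-test: (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance in paired differences; no difference detectable")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def compare_flat_vs_hierarchical(branch_texts, branch_labels, other_texts,
                                 k: int = 5, k_features: int = 100, C: float = 1.0,
                                 m: int = 10, seed: int = 0) -> dict:
    """Per-category flat vs hierarchical AUCs inside one branch.

    Hierarchical classifiers train with negatives restricted to the
    sibling documents (``branch_texts``); flat classifiers also include
    every other curatable document (``other_texts``) as negatives.  Both
    are evaluated on the same task — ranking a category's held-out
    documents above its held-out siblings — on a shared fold plan.
    """
    y = np.asarray(branch_labels)
    cats = tuple(sorted(set(y)))
    if len(cats) < 2:
        raise ValueError("branch must contain at least two categories")
    texts = list(branch_texts)
    other = list(other_texts)
    plan = kfold_plan(len(texts), k, y, seed=seed)
    hier = np.zeros((len(texts), len(cats)))
    flat = np.zeros((len(texts), len(cats)))
    for i in range(plan.k):
        train, test = plan.train_test(i)
        tr_texts = [texts[j] for j in train]
        te_texts = [texts[j] for j in test]
        for c_idx, cat in enumerate(cats):
            y_bin = (y[train] == cat).astype(int)
            vec = TfidfIgVectorizer(k=k_features).fit(tr_texts, y_bin)
            ens = SvmEnsemble(m=m, C=C, random_state=seed + i).fit(
                vec.transform(tr_texts), y_bin
            )
            hier[test, c_idx] = ens.decision_function(vec.transform(te_texts))
            flat_texts = tr_texts + other
            flat_y = np.concatenate([y_bin, np.zeros(len(other), dtype=int)])
            vec_f = TfidfIgVectorizer(k=k_features).fit(flat_texts, flat_y)
            ens_f = SvmEnsemble(m=m, C=C, random_state=seed + i).fit(
                vec_f.transform(flat_texts), flat_y
            )
            flat[test, c_idx] = ens_f.decision_function(vec_f.transform(te_texts))
    rows = []
    for c_idx, cat in enumerate(cats):
        is_cat = (y == cat).astype(int)
        rows.append({
            "category": cat,
            "n": int(is_cat.sum()),
            "flat_auc": roc_auc(flat[:, c_idx], is_cat).auc,
            "hierarchical_auc": roc_auc(hier[:, c_idx], is_cat).auc,
        })
    table = pd.DataFrame(rows)
    result = {
        "table": table,
        "mean_flat_auc": float(table["flat_auc"].mean()),
        "mean_hierarchical_auc": float(table["hierarchical_auc"].mean()),
    }
    try:
        t, df, p = paired_t_test(table["flat_auc"], table["hierarchical_auc"])
        result.update({"t": t, "df": df, "p_value": p})
    except ValueError:
        result.update({"t": 0.0, "df": len(table) - 1, "p_value": float("nan"),
                       "note": "no difference (zero-variance paired differences)"})
    return result
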