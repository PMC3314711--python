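"""Hierarchical triage cascade: Level-0 curatability, then Levels 1-3.

The cascade is greedy and top-down.  A document first receives a
curatability margin from the Level-0 ensemble; documents below the
calibrated threshold stop there.  Curatable documents are scored by the
Level-1 one-vs-rest ensembles, the combiner picks a category, and the
document descends into that branch's sibling set, repeating until the
taxonomy runs out of children or the branch skips the remaining levels.
A wrong turn at one level is never revisited at the next — this mirrors
the production pipeline, where each level's reviewers only ever see the
documents routed to them.

The Level-0 threshold is calibrated on pooled out-of-fold
cross-validation scores to hit a target sensitivity (default 95%, the
human inter-annotator disagreement rate for curatability): among all
cutoffs reaching the target sensitivity, the one with the best
specificity — and, among equals, the most conservative (highest) cutoff,
so that the achieved sensitivity tracks the target rather than
saturating at 100% on easy data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classifiers import LinearSVM, SvmEnsemble
from .combiner import (
    CostMatrix,
    CostSensitiveMLP,
    build_catchall_cost_matrix,
    build_priority_cost_matrix,
    uniform_cost_matrix,
)
from .features import FeatureSet, TfidfIgVectorizer
from .io import CURATABLE, UNCURATABLE, AbstractRecord, LabelRecord, join_corpus
from .evaluation import crossval_score_profiles, kfold_plan
from .taxonomy import NA, Taxonomy, default_taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "calibrate_level0_threshold",
    "TriageResult",
    "HierarchicalTriageClassifier",
    "train_full_hierarchy",
    "classify_document",
    "classify_corpus",
    "results_to_frame",
]


def calibrate_level0_threshold(scores, labels, target_sensitivity: float = 0.95
                               ) -> tuple[float, dict]:
    """Score cutoff reaching the target sensitivity with best specificity.

    Sweeps the midpoints of sorted unique scores plus the two infinite
    endpoints; a document is called positive when ``score >= cutoff``.
    Among cutoffs with sensitivity >= target, returns the one maximising
    specificity, ties resolved toward the highest cutoff.  If the target
    is unreachable even at the lowest cutoff, returns ``-inf`` (accept
    everything) with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("calibration needs both classes present")
    uniq = np.unique(scores)
    cuts = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best = None
    for cut in cuts:
        called = scores >= cut
        sens = (called & y).sum() / n_pos
        spec = (~called & ~y).sum() / n_neg
        if sens >= target_sensitivity:
            # >= on both: prefer higher specificity, then higher cutoff
            if best is None or (spec, cut) >= (best[1], best[2]):
                best = (sens, spec, cut)
    if best is None:
        warnings.warn(
            "target sensitivity unreachable; thresholding at -inf (accept everything)"
        )
        return float("-inf"), {"sensitivity": 1.0, "specificity": 0.0}
    sens, spec, cut = best
    return float(cut), {"sensitivity": float(sens), "specificity": float(spec)}


@dataclass(frozen=True)
class TriageResult:
    """Per-document cascade outcome."""

    pmid: str
    level0_score: float
    level0_call: str  # "curatable" | "uncuratable"
    level1: str = NA
    level2: str = NA
    level3: str = NA
    scores: dict = field(default_factory=dict)  # level -> {category: margin}
    basis: dict = field(default_factory=dict)   # level -> decision basis

    @property
    def path(self) -> tuple[str, str, str]:
        return (self.level1, self.level2, self.level3)


@dataclass
class _NodeModel:
    """Trained machinery for one sibling set (or its degenerate fallback)."""

    parent: str | None
    categories: tuple[str, ...]
    mode: str  # "model" | "majority" | "passthrough"
    vectorizers: dict = field(default_factory=dict)
    ensembles: dict = field(default_factory=dict)
    mlp: CostSensitiveMLP | None = None
    cost_matrix: CostMatrix | None = None
    majority_class: str | None = None


class HierarchicalTriageClassifier(BaseEstimator):
    """End-to-end cost-sensitive hierarchical triage model.

    ``fit`` takes parallel sequences of :class:`AbstractRecord` and
    :class:`LabelRecord` (joined on PMID) and trains the Level-0
    curatability ensemble plus one sibling-set model per taxonomy node
    with children.  Sibling-set negatives are always restricted to the
    same-parent siblings.  ``predict`` returns :class:`TriageResult`
    rows.

    Parameters
    ----------
    taxonomy : category tree; the bundled default when ``None``.
    k_features, min_df : feature selection per classification task.
    C, m : SVM regularisation and ensemble size.
    target_sensitivity : Level-0 calibration target.
    level0_cv, combiner_cv : fold counts for threshold calibration and
        for generating the combiner's out-of-fold training profiles.
    min_examples : a sibling set trains only if every category has at
        least ``max(min_examples, m)`` documents; otherwise it falls
        back to majority-class assignment.
    use_priority_costs, use_catchall_costs : enable the Level-1 priority
        matrix and the deeper-level catch-all matrices (uniform 0/1
        costs otherwise).
    """

    def __init__(self, taxonomy: Taxonomy | None = None, k_features: int = 100,
                 min_df: int = 3, C: float = 1.0, m: int = 10,
                 target_sensitivity: float = 0.95, level0_cv: int = 10,
                 combiner_cv: int = 5, min_examples: int = 5,
                 use_priority_costs: bool = True, use_catchall_costs: bool = True,
                 mlp_epochs: int = 500, mlp_lr: float = 0.3,
                 random_state: int = 0):
        self.taxonomy = taxonomy
        self.k_features = k_features
        self.min_df = min_df
        self.C = C
        self.m = m
        self.target_sensitivity = target_sensitivity
        self.level0_cv = level0_cv
        self.combiner_cv = combiner_cv
        self.min_examples = min_examples
        self.use_priority_costs = use_priority_costs
        self.use_catchall_costs = use_catchall_costs
        self.mlp_epochs = mlp_epochs
        self.mlp_lr = mlp_lr
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _cost_matrix_for(self, parent: str | None, categories) -> CostMatrix:
        tax = self.taxonomy_
        if parent is None:
            if self.use_priority_costs:
                return build_priority_cost_matrix(
                    tax.priority_partition(), categories=categories
                )
            return uniform_cost_matrix(categories)
        flags = tax.catch_all_flags(parent)
        if self.use_catchall_costs and any(flags.get(c, False) for c in categories):
            return build_catchall_cost_matrix(categories, flags)
        return uniform_cost_matrix(categories)

    @staticmethod
    def _set_membership(labels: list[LabelRecord], tax: Taxonomy,
                        parent: str | None, children) -> tuple[list[int], list[str]]:
        """Indices of curatable docs in this sibling set and their classes."""
        child_set = set(children)
        idx, cls = [], []
        for i, lab in enumerate(labels):
            if lab.level0 != CURATABLE:
                continue
            for name in (lab.level1, lab.level2, lab.level3):
                if name in child_set:
                    idx.append(i)
                    cls.append(name)
                    break
        return idx, cls

    # -- estimator API -----------------------------------------------------
    def fit(self, abstracts, labels):
        joined, report = join_corpus(list(abstracts), list(labels))
        if not joined:
            raise ValueError("empty training corpus after joining")
        self.join_report_ = report
        self.taxonomy_ = self.taxonomy if self.taxonomy is not None else default_taxonomy()
        for _, lab in joined:
            lab.validate(self.taxonomy_)
        texts = [rec.text for rec, _ in joined]
        labs = [lab for _, lab in joined]
        y0 = np.array([lab.level0 == CURATABLE for lab in labs], dtype=int)
        rng_seed = self.random_state

        # Level 0: out-of-fold scores -> threshold; final model on all data
        plan = kfold_plan(len(texts), self.level0_cv, y0, seed=rng_seed)
        oof = np.zeros(len(texts))
        for i in range(plan.k):
            train, test = plan.train_test(i)
            vec = TfidfIgVectorizer(k=self.k_features, min_df=self.min_df).fit(
                [texts[j] for j in train], y0[train]
            )
            ens = SvmEnsemble(m=self.m, C=self.C, random_state=rng_seed + i).fit(
                vec.transform([texts[j] for j in train]), y0[train]
            )
            oof[test] = ens.decision_function(vec.transform([texts[j] for j in test]))
        self.level0_threshold_, self.level0_calibration_ = calibrate_level0_threshold(
            oof, y0, self.target_sensitivity
        )
        self.level0_vectorizer_ = TfidfIgVectorizer(
            k=self.k_features, min_df=self.min_df
        ).fit(texts, y0)
        self.level0_ensemble_ = SvmEnsemble(
            m=self.m, C=self.C, random_state=rng_seed
        ).fit(self.level0_vectorizer_.transform(texts), y0)

        # sibling-set models
        self.node_models_: dict[str | None, _NodeModel] = {}
        min_per_class = max(self.min_examples, self.m)
        for parent, children in self.taxonomy_.sibling_sets():
            idx, cls = self._set_membership(labs, self.taxonomy_, parent, children)
            if not idx:
                logger.info("sibling set %r: no training documents; skipped", parent)
                continue
            counts = {c: cls.count(c) for c in children}
            if len(children) == 1:
                self.node_models_[parent] = _NodeModel(
                    parent, tuple(children), "passthrough", majority_class=children[0]
                )
                continue
            present = [c for c in children if counts[c] > 0]
            if len(present) < 2 or min(counts[c] for c in present) < min_per_class \
                    or any(counts[c] < min_per_class for c in children):
                majority = max(counts, key=lambda c: (counts[c], c))
                logger.warning(
                    "sibling set %r starved (counts %s < %d); falling back to "
                    "majority class %r", parent, counts, min_per_class, majority
                )
                self.node_models_[parent] = _NodeModel(
                    parent, tuple(children), "majority", majority_class=majority
                )
                continue
            set_texts = [texts[i] for i in idx]
            set_y = np.asarray(cls)
            cats = tuple(children)
            set_plan = kfold_plan(len(idx), self.combiner_cv, set_y, seed=rng_seed)
            profiles, _ = crossval_score_profiles(
                set_texts, set_y, set_plan, categories=cats,
                k_features=self.k_features, C=self.C, m=self.m,
                min_df=self.min_df, seed=rng_seed,
            )
            cost = self._cost_matrix_for(parent, cats)
            mlp = CostSensitiveMLP(
                epochs=self.mlp_epochs, lr=self.mlp_lr, random_state=rng_seed,
                cost_matrix=cost,
            ).fit(profiles, set_y)
            node = _NodeModel(parent, cats, "model", mlp=mlp, cost_matrix=cost)
            for cat in cats:
                y_bin = (set_y == cat).astype(int)
                vec = TfidfIgVectorizer(k=self.k_features, min_df=self.min_df).fit(
                    set_texts, y_bin
                )
                node.vectorizers[cat] = vec
                node.ensembles[cat] = SvmEnsemble(
                    m=self.m, C=self.C, random_state=rng_seed
                ).fit(vec.transform(set_texts), y_bin)
            self.node_models_[parent] = node
        return self

    # -- prediction --------------------------------------------------------
    def _decide(self, node: _NodeModel, text: str) -> tuple[str, dict, str]:
        if node.mode == "passthrough":
            return node.majority_class, {}, "passthrough"
        if node.mode == "majority":
            return node.majority_class, {}, "majority"
        profile = np.array([
            float(node.ensembles[c].decision_function(
                node.vectorizers[c].transform([text])
            )[0])
            for c in node.categories
        ])
        category = str(node.mlp.predict(profile[None, :])[0])
        basis = "min-cost" if node.mlp.min_cost_decision and node.cost_matrix is not None \
            else "argmax"
        return category, dict(zip(node.categories, profile)), basis

    def predict_one(self, record: AbstractRecord) -> TriageResult:
        score = float(self.level0_ensemble_.decision_function(
            self.level0_vectorizer_.transform([record.text])
        )[0])
        if score < self.level0_threshold_:
            return TriageResult(record.pmid, score, UNCURATABLE)
        levels = {1: NA, 2: NA, 3: NA}
        scores: dict[int, dict] = {}
        basis: dict[int, str] = {}
        parent: str | None = None
        while True:
            node = self.node_models_.get(parent)
            if node is None:
                break
            category, profile, how = self._decide(node, record.text)
            level = self.taxonomy_.node(category).level
            levels[level] = category
            if profile:
                scores[level] = profile
            basis[level] = how
            parent = category
        return TriageResult(record.pmid, score, CURATABLE,
                            levels[1], levels[2], levels[3], scores, basis)

    def predict(self, records) -> list[TriageResult]:
        return [self.predict_one(rec) for rec in records]

    # -- serialisation -----------------------------------------------------
    def to_json(self) -> dict:
        """Documented JSON container: feature sets, weights and provenance."""

        def fs_dict(fs: FeatureSet) -> dict:
            return {"terms": list(fs.terms), "ig": list(fs.ig),
                    "idf": list(fs.idf), "k": fs.k}

        def ens_dict(ens: SvmEnsemble) -> dict:
            return {
                "m": ens.m, "C": ens.C, "seed": ens.random_state,
                "classes": np.asarray(ens.classes_).tolist(),
                "members": [
                    {"coef": mem.coef_.tolist(), "intercept": mem.intercept_}
                    for mem in ens.members_
                ],
            }

        def mlp_dict(mlp: CostSensitiveMLP) -> dict:
            return {
                "W1": mlp.W1_.tolist(), "b1": mlp.b1_.tolist(),
                "W2": mlp.W2_.tolist(), "b2": mlp.b2_.tolist(),
                "mean": mlp.mean_.tolist(), "scale": mlp.scale_.tolist(),
                "classes": np.asarray(mlp.classes_).tolist(),
                "epochs": mlp.epochs, "lr": mlp.lr, "momentum": mlp.momentum,
                "seed": mlp.random_state, "reweight": mlp.reweight,
                "min_cost_decision": mlp.min_cost_decision,
            }

        nodes = {}
        for parent, node in self.node_models_.items():
            entry: dict = {"categories": list(node.categories), "mode": node.mode}
            if node.mode == "model":
                entry["vectorizers"] = {
                    c: fs_dict(v.feature_set_) for c, v in node.vectorizers.items()
                }
                entry["ensembles"] = {c: ens_dict(e) for c, e in node.ensembles.items()}
                entry["mlp"] = mlp_dict(node.mlp)
                entry["cost_matrix"] = {
                    "categories": list(node.cost_matrix.categories),
                    "matrix": node.cost_matrix.matrix.tolist(),
                }
            else:
                entry["majority_class"] = node.majority_class
            nodes[parent if parent is not None else "__root__"] = entry
        return {
            "format": "litriage-bundle/1",
            "params": {k: v for k, v in self.get_params().items() if k != "taxonomy"},
            "taxonomy": self.taxonomy_.to_dict(),
            "level0": {
                "threshold": self.level0_threshold_,
                "calibration": self.level0_calibration_,
                "feature_set": fs_dict(self.level0_vectorizer_.feature_set_),
                "ensemble": ens_dict(self.level0_ensemble_),
            },
            "nodes": nodes,
        }

    @classmethod
    def from_json(cls, data: dict) -> "HierarchicalTriageClassifier":
        from .taxonomy import load_taxonomy

        def fs_from(d) -> FeatureSet:
            return FeatureSet(tuple(d["terms"]), tuple(d["ig"]), tuple(d["idf"]), d["k"])

        def ens_from(d) -> SvmEnsemble:
            ens = SvmEnsemble(m=d["m"], C=d["C"], random_state=d["seed"])
            ens.classes_ = np.asarray(d["classes"])
            ens.members_ = [
                LinearSVM.from_weights(mem["coef"], mem["intercept"],
                                       classes=d["classes"], C=d["C"])
                for mem in d["members"]
            ]
            return ens

        def mlp_from(d, cost) -> CostSensitiveMLP:
            mlp = CostSensitiveMLP(
                epochs=d["epochs"], lr=d["lr"], momentum=d["momentum"],
                random_state=d["seed"], cost_matrix=cost,
                reweight=d["reweight"], min_cost_decision=d["min_cost_decision"],
            )
            mlp.W1_ = np.asarray(d["W1"]); mlp.b1_ = np.asarray(d["b1"])
            mlp.W2_ = np.asarray(d["W2"]); mlp.b2_ = np.asarray(d["b2"])
            mlp.mean_ = np.asarray(d["mean"]); mlp.scale_ = np.asarray(d["scale"])
            mlp.classes_ = np.asarray(d["classes"])
            return mlp

        if data.get("format") != "litriage-bundle/1":
            raise ValueError("not a litriage model bundle")
        model = cls(**data["params"])
        model.taxonomy_ = load_taxonomy(data["taxonomy"])
        l0 = data["level0"]
        model.level0_threshold_ = l0["threshold"]
        model.level0_calibration_ = l0["calibration"]
        model.level0_vectorizer_ = TfidfIgVectorizer.from_feature_set(
            fs_from(l0["feature_set"]), min_df=model.min_df
        )
        model.level0_ensemble_ = ens_from(l0["ensemble"])
        model.node_models_ = {}
        for key, entry in data["nodes"].items():
            parent = None if key == "__root__" else key
            cats = tuple(entry["categories"])
            if entry["mode"] == "model":
                cost = CostMatrix(tuple(entry["cost_matrix"]["categories"]),
                                  np.asarray(entry["cost_matrix"]["matrix"]))
                node = _NodeModel(parent, cats, "model", cost_matrix=cost,
                                  mlp=mlp_from(entry["mlp"], cost))
                for c in cats:
                    node.vectorizers[c] = TfidfIgVectorizer.from_feature_set(
                        fs_from(entry["vectorizers"][c]), min_df=model.min_df
                    )
                    node.ensembles[c] = ens_from(entry["ensembles"][c])
            else:
                node = _NodeModel(parent, cats, entry["mode"],
                                  majority_class=entry["majority_class"])
            model.node_models_[parent] = node
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def load(cls, path) -> "HierarchicalTriageClassifier":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


# ---------------------------------------------------------------------------
# functional wrappers and corpus-level reporting

def train_full_hierarchy(abstracts, labels, taxonomy: Taxonomy | None = None,
                         **params) -> HierarchicalTriageClassifier:
    return HierarchicalTriageClassifier(taxonomy=taxonomy, **params).fit(abstracts, labels)


def classify_document(model: HierarchicalTriageClassifier,
                      record: AbstractRecord) -> TriageResult:
    return model.predict_one(record)


def classify_corpus(model: HierarchicalTriageClassifier, records
                    ) -> tuple[list[TriageResult], dict]:
    """Classify every record and summarise per-level counts.

    The summary counts each level's category assignments (``NA``
    included, so counts sum to the corpus size) plus the Level-1
    priority breakdown of curatable calls.
    """
    results = model.predict(list(records))
    summary: dict = {"n_documents": len(results),
                     "level0": {CURATABLE: 0, UNCURATABLE: 0},
                     "level1": {}, "level2": {}, "level3": {}}
    partition = model.taxonomy_.priority_partition()
    pred_high = pred_low = 0
    for res in results:
        summary["level0"][res.level0_call] += 1
        for level, cat in ((1, res.level1), (2, res.level2), (3, res.level3)):
            key = f"level{level}"
            summary[key][cat] = summary[key].get(cat, 0) + 1
        if res.level1 != NA:
            if partition.priority_of(res.level1) == "high":
                pred_high += 1
            else:
                pred_low += 1
    summary["priority"] = {"predicted_high": pred_high, "predicted_low": pred_low}
    return results, summary


def results_to_frame(results: list[TriageResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        rows.append({
            "pmid": res.pmid,
            "level0_score": res.level0_score,
            "level0_call": res.level0_call,
            "level1": res.level1,
            "level2": res.level2,
            "level3": res.level3,
            "basis": ";".join(f"{k}:{v}" for k, v in sorted(res.basis.items())),
        })
    return pd.DataFrame(rows, columns=["pmid", "level0_score", "level0_call",
                                       "level1", "level2", "level3", "basis"])
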