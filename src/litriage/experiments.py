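"""Synthetic-recovery studies: does the pipeline behave as designed?

Full-scale results in this problem domain require tens of thousands of
real abstracts, so the package validates its machinery on generated
corpora instead.  Each study here isolates one designed behaviour at
desk scale:

* Level-1 category recovery — every one-vs-rest ensemble separates its
  category from the siblings (out-of-fold AUC) at the generator's
  default signal strength;
* hierarchical vs flat training — restricting negatives to same-parent
  siblings does not hurt, and typically helps, within-branch ranking;
* priority cost matrix — fewer truly high-priority documents land in
  low-priority categories than under uniform costs (at the price of
  more low-to-high errors);
* catch-all cost matrix — fewer documents are predicted into the
  "Other" bucket;
* Level-0 calibration — the held-out sensitivity tracks the 95% target.

Problem sizes are chosen so each study runs in well under a few minutes
on one core: 5-fold profile generation, ~2,000-document corpora for the
Level-1 study, and a few hundred documents for the directional studies.
"""

from __future__ import annotations

import numpy as np

from .cascade import calibrate_level0_threshold
from .classifiers import SvmEnsemble
from .combiner import (
    CostSensitiveMLP,
    build_catchall_cost_matrix,
    build_priority_cost_matrix,
    uniform_cost_matrix,
)
from .evaluation import (
    compare_flat_vs_hierarchical,
    crossval_score_profiles,
    kfold_plan,
    roc_auc,
)
from .features import TfidfIgVectorizer
from .io import CURATABLE
from .synthetic import (
    GeneratorConfig,
    catchall_sibling_corpus,
    confusable_pair_corpus,
    generate_corpus,
)
from .taxonomy import default_taxonomy, load_taxonomy

__all__ = [
    "level1_recovery",
    "flat_vs_hier_recovery",
    "priority_cost_recovery",
    "catchall_cost_recovery",
    "level0_calibration_recovery",
]


def level1_recovery(seed: int, docs_per_leaf: int = 63, folds: int = 5) -> dict:
    """Out-of-fold AUC per Level-1 category on a default-strength corpus.

    Uses the bundled default taxonomy with the Infectious Disease branch
    up-weighted (the dominant branch in real triage corpora); the
    default quotas put roughly 2,000 documents in the corpus.
    """
    tax = default_taxonomy()
    cfg = GeneratorConfig(seed=seed, docs_per_leaf=docs_per_leaf,
                          leaf_weights={"Infectious Disease": 6.0})
    abstracts, labels = generate_corpus(tax, cfg)
    cur = [(a.text, l.level1) for a, l in zip(abstracts, labels)
           if l.level0 == CURATABLE]
    texts = [t for t, _ in cur]
    y = np.array([c for _, c in cur])
    plan = kfold_plan(len(texts), folds, y, seed=seed)
    cats = tuple(tax.level1())
    profiles, _ = crossval_score_profiles(texts, y, plan, categories=cats, seed=seed)
    aucs = {cat: roc_auc(profiles[:, j], (y == cat).astype(int)).auc
            for j, cat in enumerate(cats)}
    return {"n_documents": len(abstracts), "n_curatable": len(texts),
            "auc_per_category": aucs, "min_auc": min(aucs.values())}


def flat_vs_hier_recovery(seed: int, docs_per_leaf: int = 30) -> dict:
    """Flat vs sibling-negative training on a two-branch nested corpus."""
    tax = load_taxonomy({"level1": [
        {"name": "BranchA", "priority": "high",
         "children": [{"name": "A1"}, {"name": "A2"}, {"name": "A3"}]},
        {"name": "BranchB", "priority": "low",
         "children": [{"name": "B1"}, {"name": "B2"}, {"name": "B3"}]},
    ]})
    cfg = GeneratorConfig(seed=seed, docs_per_leaf=docs_per_leaf,
                          uncuratable_fraction=0.0)
    abstracts, labels = generate_corpus(tax, cfg)
    branch_texts = [a.text for a, l in zip(abstracts, labels) if l.level1 == "BranchA"]
    branch_labels = [l.level2 for a, l in zip(abstracts, labels) if l.level1 == "BranchA"]
    other_texts = [a.text for a, l in zip(abstracts, labels) if l.level1 != "BranchA"]
    res = compare_flat_vs_hierarchical(branch_texts, branch_labels, other_texts,
                                       k=5, seed=seed)
    return {"mean_flat_auc": res["mean_flat_auc"],
            "mean_hierarchical_auc": res["mean_hierarchical_auc"],
            "hierarchical_not_worse":
                res["mean_hierarchical_auc"] >= res["mean_flat_auc"] - 1e-12,
            "n_branch_documents": len(branch_texts)}


def _oof_profiles(texts, y, cats, seed, folds=5):
    plan = kfold_plan(len(texts), folds, y, seed=seed)
    profiles, _ = crossval_score_profiles(texts, y, plan, categories=cats, seed=seed)
    return profiles


def priority_cost_recovery(seed: int) -> dict:
    """High-to-low misrouting with vs without the priority cost matrix.

    Runs the confusable-pair preset (shared signal vocabulary, 10:1
    imbalance toward the low-priority category), trains the combiner on
    pooled out-of-fold profiles under uniform and under priority costs,
    and counts truly-high documents predicted low by each.
    """
    texts, y, tax = confusable_pair_corpus(seed)
    cats = tuple(tax.level1())  # ("HighDisease", "LowDisease")
    profiles = _oof_profiles(texts, y, cats, seed)
    uniform = CostSensitiveMLP(cost_matrix=uniform_cost_matrix(cats),
                               random_state=seed).fit(profiles, y)
    priority = CostSensitiveMLP(
        cost_matrix=build_priority_cost_matrix(tax.priority_partition(),
                                               categories=cats),
        random_state=seed,
    ).fit(profiles, y)
    high = y == "HighDisease"
    errs = {
        "uniform": int((uniform.predict(profiles)[high] == "LowDisease").sum()),
        "cost_sensitive": int((priority.predict(profiles)[high] == "LowDisease").sum()),
    }
    errs["n_high"] = int(high.sum())
    errs["n_documents"] = len(texts)
    return errs


def catchall_cost_recovery(seed: int) -> dict:
    """Predictions into the catch-all bucket with vs without its cost matrix."""
    texts, y, flags = catchall_sibling_corpus(seed)
    cats = tuple(flags)
    profiles = _oof_profiles(texts, y, cats, seed)
    uniform = CostSensitiveMLP(cost_matrix=uniform_cost_matrix(cats),
                               random_state=seed).fit(profiles, y)
    catchall = CostSensitiveMLP(
        cost_matrix=build_catchall_cost_matrix(cats, flags),
        random_state=seed,
    ).fit(profiles, y)
    return {
        "uniform": int((uniform.predict(profiles) == "OTH").sum()),
        "cost_sensitive": int((catchall.predict(profiles) == "OTH").sum()),
        "n_true_catchall": int((y == "OTH").sum()),
        "n_documents": len(texts),
    }


def level0_calibration_recovery(seed: int, docs_per_leaf: int = 40,
                                test_fraction: float = 0.25,
                                target: float = 0.95) -> dict:
    """Held-out Level-0 sensitivity at the cross-validation-calibrated cutoff."""
    tax = default_taxonomy()
    cfg = GeneratorConfig(seed=seed, docs_per_leaf=docs_per_leaf)
    abstracts, labels = generate_corpus(tax, cfg)
    texts = [a.text for a in abstracts]
    y = np.array([l.level0 == CURATABLE for l in labels], dtype=int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_test = int(len(y) * test_fraction)
    test_idx, train_idx = order[:n_test], order[n_test:]
    tr_texts = [texts[i] for i in train_idx]
    tr_y = y[train_idx]

    plan = kfold_plan(len(tr_texts), 10, tr_y, seed=seed)
    oof = np.zeros(len(tr_texts))
    for i in range(plan.k):
        tr, te = plan.train_test(i)
        vec = TfidfIgVectorizer().fit([tr_texts[j] for j in tr], tr_y[tr])
        ens = SvmEnsemble(random_state=seed + i).fit(
            vec.transform([tr_texts[j] for j in tr]), tr_y[tr]
        )
        oof[te] = ens.decision_function(vec.transform([tr_texts[j] for j in te]))
    threshold, cal = calibrate_level0_threshold(oof, tr_y, target)

    vec = TfidfIgVectorizer().fit(tr_texts, tr_y)
    ens = SvmEnsemble(random_state=seed).fit(vec.transform(tr_texts), tr_y)
    te_scores = ens.decision_function(vec.transform([texts[i] for i in test_idx]))
    te_y = y[test_idx].astype(bool)
    called = te_scores >= threshold
    sens = float((called & te_y).sum() / te_y.sum())
    spec = float((~called & ~te_y).sum() / (~te_y).sum())
    return {"threshold": threshold, "calibration": cal,
            "heldout_sensitivity": sens, "heldout_specificity": spec,
            "n_train": len(tr_texts), "n_test": n_test,
            "n_test_positives": int(te_y.sum()), "target": target}
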