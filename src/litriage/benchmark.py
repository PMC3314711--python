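"""Arithmetic over the bundled independent-benchmark summary fixtures.

The package ships small plain-text fixtures summarising the published
independent-benchmark outcome of the triage system (1,388 abstracts
retrieved in one quarterly query): the Level-1 confusion matrix of the
287 confirmed-curatable abstracts, the Level-0 outcome counts, the
per-branch Level-2/3 agreement counts, and the seven flat-vs-hierarchical
AUC pairs from the Autoimmunity comparison.  The functions here
recompute the headline percentages and the paired t-test from those raw
counts; nothing is hard-coded beyond the fixtures themselves.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .evaluation import (
    accuracy_from_confusion,
    paired_t_test,
    priority_breakdown,
    sensitivity_specificity,
)
from .taxonomy import default_taxonomy

__all__ = [
    "load_level1_confusion",
    "load_level0_counts",
    "load_level23_counts",
    "load_flat_vs_hier_auc",
    "benchmark_report",
]


def _fixture(name: str):
    return importlib.resources.files("litriage.data") / name


def load_level1_confusion() -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(_fixture("benchmark_level1_confusion.tsv"), sep="\t", comment="#")
    cats = df["expert"].tolist()
    return cats, df[cats].to_numpy(dtype=float)


def load_level0_counts() -> dict[str, int]:
    df = pd.read_csv(_fixture("benchmark_level0_counts.tsv"), sep="\t", comment="#")
    return dict(zip(df["outcome"], df["count"].astype(int)))


def load_level23_counts() -> pd.DataFrame:
    return pd.read_csv(_fixture("benchmark_level23_counts.tsv"), sep="\t",
                       comment="#", na_values=["NA"])


def load_flat_vs_hier_auc() -> pd.DataFrame:
    return pd.read_csv(_fixture("benchmark_flat_vs_hier_auc.tsv"), sep="\t", comment="#")


def benchmark_report() -> dict:
    """All headline benchmark figures, recomputed from the raw fixtures.

    Percentages are on the 0-100 scale; AUC means and the p-value are
    plain fractions.
    """
    cats, conf = load_level1_confusion()
    partition = default_taxonomy().priority_partition()
    pb = priority_breakdown(conf, cats, partition)

    l0 = load_level0_counts()
    sens, spec = sensitivity_specificity(
        tp=l0["predicted_curatable_confirmed"],
        fn=l0["predicted_uncuratable_missed"],
        fp=l0["predicted_curatable_rejected"],
        tn=l0["predicted_uncuratable_confirmed"],
    )

    l23 = load_level23_counts()
    m2 = l23["level2_correct"].notna()
    m3 = l23["level3_correct"].notna()
    level2_acc = l23.loc[m2, "level2_correct"].sum() / l23.loc[m2, "assigned_by_expert"].sum()
    level3_acc = l23.loc[m3, "level3_correct"].sum() / l23.loc[m3, "assigned_by_expert"].sum()

    auc = load_flat_vs_hier_auc()
    t, df_, p = paired_t_test(auc["flat_auc"], auc["hierarchical_auc"])

    return {
        "level1_accuracy_pct": 100 * accuracy_from_confusion(conf),
        "level1_correct": float(np.trace(conf)),
        "level1_total": float(conf.sum()),
        "high_priority_accuracy_pct": 100 * pb["pct_correct_high"],
        "low_priority_accuracy_pct": 100 * pb["pct_correct_low"],
        "true_high_predicted_low": pb["high_pred_low"],
        "predicted_high_total": pb["n_pred_high"],
        "level0_sensitivity_pct": 100 * sens,
        "level0_specificity_pct": 100 * spec,
        "level2_accuracy_pct": 100 * float(level2_acc),
        "level3_accuracy_pct": 100 * float(level3_acc),
        "mean_flat_auc": float(auc["flat_auc"].mean()),
        "mean_hierarchical_auc": float(auc["hierarchical_auc"].mean()),
        "flat_vs_hier_t": t,
        "flat_vs_hier_p": p,
    }
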