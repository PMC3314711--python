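"""Synthetic labeled abstract corpora with hierarchical topic structure.

Real triage corpora are PMID lists whose text must be fetched, so every
training and evaluation path in this package is exercised instead on
generated corpora that emulate the structure the classifiers assume: a
shared background vocabulary with Zipf-distributed frequencies, a small
disjoint signal vocabulary per taxonomy node (uniform within the node,
which keeps information-gain arithmetic tractable in tests), a separate
curatability signal, and tunable class imbalance and signal strength.

A curatable document's tokens are background draws with probability
``alpha`` and otherwise come uniformly from one of its label path's
signal vocabularies (Level-1 node, deeper nodes, and the generic
curatability node).  Uncuratable documents mix background with a
disjoint "uncuratable" vocabulary.  All randomness flows from the single
config seed through numpy ``SeedSequence`` spawning, so any corpus is
reproducible from its manifest alone.

Two purpose-built presets support the cost-sensitivity analyses: a
*confusable pair* of Level-1 categories that share a fraction of their
signal terms (deliberately relaxing the disjoint-vocabulary rule) with
high/low priority flags and imbalance, and a *catch-all* sibling set
whose "Other" bucket emits pure background noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    CURATABLE,
    UNCURATABLE,
    AbstractRecord,
    LabelRecord,
    write_abstracts,
    write_label_table,
)
from .taxonomy import NA, Taxonomy, load_taxonomy

__all__ = [
    "GeneratorConfig",
    "TopicModel",
    "build_topic_model",
    "sample_document",
    "generate_corpus",
    "generate_benchmark",
    "confusable_pair_corpus",
    "catchall_sibling_corpus",
]

_CUR = "__curatable__"
_UNC = "__uncuratable__"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus generation.

    Defaults: 25% of documents uncuratable (the published corpus is
    ~25% curatable overall, but the triage-relevant imbalance here is a
    minority class at Level 0 either way), signal fraction ``1 - alpha``
    of 30%, mean document length 150 tokens, 20 signal terms per node,
    2,000 background terms.
    """

    seed: int
    docs_per_leaf: int = 50
    uncuratable_fraction: float = 0.25
    doc_length: float = 150.0
    alpha: float = 0.7
    s: int = 20
    v_bg: int = 2000
    term_space: int = 1_000_000
    leaf_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.uncuratable_fraction < 1.0):
            raise ValueError("uncuratable_fraction must be in [0, 1)")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.doc_length <= 0:
            raise ValueError("doc_length must be positive")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "docs_per_leaf": self.docs_per_leaf,
            "uncuratable_fraction": self.uncuratable_fraction,
            "doc_length": self.doc_length, "alpha": self.alpha, "s": self.s,
            "v_bg": self.v_bg, "term_space": self.term_space,
            "leaf_weights": dict(self.leaf_weights),
        }


@dataclass(frozen=True)
class TopicModel:
    """Term distributions: Zipf background plus per-node uniform signals."""

    background_terms: tuple[str, ...]
    background_probs: np.ndarray
    node_terms: dict  # node name (incl. _CUR/_UNC) -> tuple of terms
    alpha: float

    def signal_terms(self, node: str) -> tuple[str, ...]:
        return self.node_terms[node]


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name.lower())


def build_topic_model(taxonomy: Taxonomy, config: GeneratorConfig) -> TopicModel:
    """Deterministic topic model over the taxonomy's nodes.

    Node signal vocabularies are pairwise disjoint (distinct name
    prefixes) and disjoint from the background.
    """
    nodes = list(taxonomy.nodes) + [_CUR, _UNC]
    needed = config.s * len(nodes) + config.v_bg
    if needed > config.term_space:
        raise ValueError(
            f"term space exhausted: need {needed} terms, term_space={config.term_space}"
        )
    bg = tuple(f"bg{i:05d}" for i in range(config.v_bg))
    ranks = np.arange(1, config.v_bg + 1, dtype=float)
    probs = (1.0 / ranks) / (1.0 / ranks).sum()
    node_terms = {
        node: tuple(f"sig{_slug(node)}x{j:03d}" for j in range(config.s))
        for node in nodes
    }
    return TopicModel(bg, probs, node_terms, config.alpha)


def _draw_tokens(model: TopicModel, signal_nodes: list[str], length: int,
                 rng: np.random.Generator) -> list[str]:
    if length == 0:
        return []
    from_bg = rng.random(length) < model.alpha if signal_nodes \
        else np.ones(length, dtype=bool)
    n_bg = int(from_bg.sum())
    bg_draws = rng.choice(len(model.background_terms), size=n_bg,
                          p=model.background_probs)
    tokens = []
    bg_iter = iter(bg_draws)
    for is_bg in from_bg:
        if is_bg:
            tokens.append(model.background_terms[next(bg_iter)])
        else:
            node = signal_nodes[rng.integers(len(signal_nodes))]
            terms = model.node_terms[node]
            tokens.append(terms[rng.integers(len(terms))])
    return tokens


def sample_document(model: TopicModel, taxonomy: Taxonomy, leaf: str | None,
                    pmid: str, rng: np.random.Generator,
                    doc_length: float = 150.0) -> tuple[AbstractRecord, LabelRecord]:
    """One document for a leaf's label path (``None`` = uncuratable)."""
    if leaf is None:
        signal_nodes = [_UNC]
        label = LabelRecord(pmid, UNCURATABLE)
    else:
        signal_nodes = taxonomy.path_to(leaf) + [_CUR]
        l1, l2, l3 = taxonomy.path_levels(leaf)
        label = LabelRecord(pmid, CURATABLE, l1, l2, l3)
    length = max(1, int(rng.poisson(doc_length)))
    tokens = _draw_tokens(model, signal_nodes, length, rng)
    n_title = min(8, len(tokens))
    return (
        AbstractRecord(pmid, " ".join(tokens[:n_title]), " ".join(tokens[n_title:])),
        label,
    )


def generate_corpus(taxonomy: Taxonomy, config: GeneratorConfig
                    ) -> tuple[list[AbstractRecord], list[LabelRecord]]:
    """Full labeled corpus: every leaf gets its quota, plus uncuratable noise.

    The uncuratable block is sized so it makes up ``uncuratable_fraction``
    of the final corpus.  ``leaf_weights`` multiplies a leaf's quota to
    emulate dominant branches.
    """
    model = build_topic_model(taxonomy, config)
    ss = np.random.SeedSequence(config.seed)
    leaves = taxonomy.leaves()
    quotas = [
        max(1, int(round(config.docs_per_leaf * config.leaf_weights.get(l, 1.0))))
        for l in leaves
    ]
    n_cur = sum(quotas)
    n_unc = int(round(n_cur * config.uncuratable_fraction / (1 - config.uncuratable_fraction)))
    abstracts, labels = [], []
    pmid = 9000001
    child_seeds = ss.spawn(n_cur + n_unc)
    k = 0
    for leaf, quota in zip(leaves, quotas):
        for _ in range(quota):
            rng = np.random.default_rng(child_seeds[k]); k += 1
            rec, lab = sample_document(model, taxonomy, leaf, str(pmid), rng,
                                       config.doc_length)
            abstracts.append(rec); labels.append(lab); pmid += 1
    for _ in range(n_unc):
        rng = np.random.default_rng(child_seeds[k]); k += 1
        rec, lab = sample_document(model, taxonomy, None, str(pmid), rng,
                                   config.doc_length)
        abstracts.append(rec); labels.append(lab); pmid += 1
    return abstracts, labels


def generate_benchmark(taxonomy: Taxonomy, config: GeneratorConfig, outdir,
                       force: bool = False) -> dict:
    """Write a benchmark corpus (MEDLINE + label TSV + JSON manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": outdir / "corpus.medline",
        "labels": outdir / "labels.tsv",
        "manifest": outdir / "manifest.json",
    }
    clashes = [str(p) for p in paths.values() if p.exists()]
    if clashes and not force:
        raise FileExistsError(f"output exists (use force=True): {clashes}")
    abstracts, labels = generate_corpus(taxonomy, config)
    write_abstracts(paths["corpus"], abstracts, format="medline")
    write_label_table(paths["labels"], labels)
    manifest = {
        "generator": "litriage.synthetic",
        "config": config.to_dict(),
        "taxonomy": taxonomy.to_dict(),
        "n_documents": len(abstracts),
        "n_curatable": sum(l.level0 == CURATABLE for l in labels),
        "files": {k: p.name for k, p in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def regenerate_from_manifest(manifest_path, outdir, force: bool = False) -> dict:
    """Rebuild a benchmark byte-identically from its manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg = GeneratorConfig(**manifest["config"])
    tax = load_taxonomy(manifest["taxonomy"])
    return generate_benchmark(tax, cfg, outdir, force=force)


# ---------------------------------------------------------------------------
# purpose-built presets for the cost-sensitivity analyses

def confusable_pair_corpus(seed: int, n_high: int = 60, n_low: int = 600,
                           shared_fraction: float = 0.9, alpha: float = 0.9,
                           s: int = 20, v_bg: int = 1000,
                           doc_length: float = 100.0,
                           ) -> tuple[list[str], np.ndarray, Taxonomy]:
    """Two confusable Level-1 categories with a 10:1 priority imbalance.

    ``HighDisease`` (high priority, rare) and ``LowDisease`` (low
    priority, dominant) share ``shared_fraction`` of their signal terms,
    so borderline documents genuinely straddle the boundary — the regime
    where the priority cost matrix changes decisions.  Returns (texts,
    category labels, taxonomy).
    """
    tax = load_taxonomy({"level1": [
        {"name": "HighDisease", "priority": "high"},
        {"name": "LowDisease", "priority": "low"},
    ]})
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_shared = int(round(s * shared_fraction))
    shared = [f"sigsharedx{j:03d}" for j in range(n_shared)]
    vocab = {
        "HighDisease": tuple(shared + [f"sighighx{j:03d}" for j in range(s - n_shared)]),
        "LowDisease": tuple(shared + [f"siglowx{j:03d}" for j in range(s - n_shared)]),
    }
    bg = tuple(f"bg{i:05d}" for i in range(v_bg))
    ranks = np.arange(1, v_bg + 1, dtype=float)
    probs = (1.0 / ranks) / (1.0 / ranks).sum()
    model = TopicModel(bg, probs, vocab, alpha)
    texts, labels = [], []
    for cat, n in (("HighDisease", n_high), ("LowDisease", n_low)):
        for _ in range(n):
            length = max(1, int(rng.poisson(doc_length)))
            texts.append(" ".join(_draw_tokens(model, [cat], length, rng)))
            labels.append(cat)
    return texts, np.asarray(labels), tax


def catchall_sibling_corpus(seed: int, n_specific: int = 80, n_catchall: int = 80,
                            s: int = 20, v_bg: int = 1000, alpha: float = 0.8,
                            doc_length: float = 100.0,
                            ) -> tuple[list[str], np.ndarray, dict]:
    """A sibling set with three specific categories and an "Other" bucket.

    Catch-all documents are pure background (no signal vocabulary of
    their own), emulating the heterogeneity of real "Other" buckets.
    Returns (texts, labels, catch_all flags).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cats = ["SpecA", "SpecB", "SpecC"]
    vocab = {c: tuple(f"sig{c.lower()}x{j:03d}" for j in range(s)) for c in cats}
    bg = tuple(f"bg{i:05d}" for i in range(v_bg))
    ranks = np.arange(1, v_bg + 1, dtype=float)
    probs = (1.0 / ranks) / (1.0 / ranks).sum()
    model = TopicModel(bg, probs, vocab, alpha)
    noise_model = TopicModel(bg, probs, vocab, 1.0)  # catch-all: background only
    texts, labels = [], []
    for cat in cats:
        for _ in range(n_specific):
            length = max(1, int(rng.poisson(doc_length)))
            texts.append(" ".join(_draw_tokens(model, [cat], length, rng)))
            labels.append(cat)
    for _ in range(n_catchall):
        length = max(1, int(rng.poisson(doc_length)))
        texts.append(" ".join(_draw_tokens(noise_model, [], length, rng)))
        labels.append("OTH")
    flags = {c: False for c in cats}
    flags["OTH"] = True
    return texts, np.asarray(labels), flags
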