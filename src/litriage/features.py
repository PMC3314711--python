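"""Bag-of-words features: tokenisation, IG-ranked selection, TF-IDF vectors.

The representation is deliberately simple, matching what era-standard
abstract classifiers used: lowercased unigrams with a PubMed stopword
list, a rare-word filter (a term must appear in at least three
documents), information-gain ranking of terms against the binary task
label, and TF x IDF weights with optional unit-length normalisation.

Feature selection is a per-task operation: each binary classifier
(curatable-vs-not, or one category against its siblings) selects its own
top-``k`` terms from its own training documents only.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "load_stopwords",
    "tokenize",
    "Vocabulary",
    "build_vocabulary",
    "idf",
    "information_gain",
    "FeatureSet",
    "select_top_k",
    "vectorize",
    "TfidfIgVectorizer",
]

_TOKEN_RE = re.compile(r"[^a-z0-9]+")


def load_stopwords() -> frozenset[str]:
    """The bundled PubMed/NCBI stopword list."""
    ref = importlib.resources.files("litriage.data") / "stopwords.txt"
    words = [
        line.strip()
        for line in ref.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return frozenset(words)


def tokenize(text: str, stopwords: frozenset[str] | None = None) -> list[str]:
    """Lowercased alphanumeric tokens with stopwords removed.

    Tokens shorter than two characters and pure-digit tokens are
    dropped.  Order is preserved; the function is idempotent on its own
    space-joined output.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    tokens = []
    for tok in _TOKEN_RE.split(text.lower()):
        if len(tok) < 2 or tok.isdigit() or tok in stopwords:
            continue
        tokens.append(tok)
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Document frequencies over a corpus after the rare-word filter."""

    df: dict[str, int]
    n_docs: int

    def __contains__(self, term: str) -> bool:
        return term in self.df


def build_vocabulary(token_docs: list[list[str]], min_df: int = 3) -> Vocabulary:
    """Document-frequency table; terms in fewer than ``min_df`` docs dropped."""
    if min_df < 1:
        raise ValueError(f"min_df must be >= 1, got {min_df}")
    if not token_docs:
        raise ValueError("empty corpus")
    df: dict[str, int] = {}
    for tokens in token_docs:
        for term in set(tokens):
            df[term] = df.get(term, 0) + 1
    return Vocabulary({t: c for t, c in df.items() if c >= min_df}, len(token_docs))


def idf(term: str, vocabulary: Vocabulary) -> float:
    """Inverse document frequency, ln(N/df)."""
    if term not in vocabulary.df:
        raise KeyError(f"term {term!r} not in vocabulary")
    return float(np.log(vocabulary.n_docs / vocabulary.df[term]))


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(term: str, token_docs: list[list[str]], labels) -> float:
    """Information gain of a term's presence for a binary document label.

    IG(t) = H(C) - [P(t) H(C|t) + P(not t) H(C|not t)], entropies in bits.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("information gain needs both labels present")
    present = np.array([term in set(toks) for toks in token_docs])
    n = len(token_docs)
    h_c = _entropy(np.array([(y == c).sum() for c in classes]))
    h_cond = 0.0
    for mask in (present, ~present):
        if mask.any():
            h_cond += mask.mean() * _entropy(
                np.array([((y == c) & mask).sum() for c in classes])
            )
    return h_c - h_cond


@dataclass(frozen=True)
class FeatureSet:
    """Ordered selected terms with their IG scores and IDF weights."""

    terms: tuple[str, ...]
    ig: tuple[float, ...]
    idf: tuple[float, ...]
    k: int

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term\tig\tidf\n")
            for t, g, w in zip(self.terms, self.ig, self.idf):
                fh.write(f"{t}\t{g:.10g}\t{w:.10g}\n")


def select_top_k(
    ig_scores: dict[str, float], vocabulary: Vocabulary, k: int = 100
) -> FeatureSet:
    """The ``k`` highest-IG terms; ties broken lexicographically."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(ig_scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    terms = tuple(t for t, _ in ranked)
    return FeatureSet(
        terms=terms,
        ig=tuple(g for _, g in ranked),
        idf=tuple(idf(t, vocabulary) for t in terms),
        k=k,
    )


def vectorize(tokens: list[str], feature_set: FeatureSet, normalize: bool = True) -> np.ndarray:
    """TF x IDF vector over the feature set, optionally unit-length."""
    vec = np.zeros(len(feature_set.terms))
    index = feature_set.index
    for tok in tokens:
        j = index.get(tok)
        if j is not None:
            vec[j] += 1.0
    vec *= np.asarray(feature_set.idf)
    if normalize:
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
    return vec


class TfidfIgVectorizer(BaseEstimator, TransformerMixin):
    """Task-specific TF-IDF vectorizer with information-gain selection.

    ``fit`` requires the binary task labels ``y`` because the top-``k``
    terms are ranked by their information gain for that task.  Transform
    produces a sparse CSR matrix of TF x IDF weights, unit-normalised by
    default.

    Parameters
    ----------
    k : number of features to keep (IG-ranked).
    min_df : rare-word filter; a term must appear in at least this many
        training documents.
    normalize : scale each document vector to unit Euclidean length.
    stopwords : stopword set; defaults to the bundled PubMed list.
    """

    def __init__(self, k: int = 100, min_df: int = 3, normalize: bool = True,
                 stopwords: frozenset[str] | None = None):
        self.k = k
        self.min_df = min_df
        self.normalize = normalize
        self.stopwords = stopwords

    @classmethod
    def from_feature_set(cls, feature_set: FeatureSet, normalize: bool = True,
                         min_df: int = 3) -> "TfidfIgVectorizer":
        """Rebuild a fitted vectorizer from a stored feature set."""
        vec = cls(k=feature_set.k, min_df=min_df, normalize=normalize)
        vec.feature_set_ = feature_set
        vec._stop = load_stopwords()
        return vec

    def fit(self, texts, y):
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("feature selection needs both task labels present")
        stop = self.stopwords if self.stopwords is not None else load_stopwords()
        token_docs = [tokenize(t, stop) for t in texts]
        vocab = build_vocabulary(token_docs, self.min_df)
        # vectorised IG over the whole vocabulary: presence counts per class
        terms = sorted(vocab.df)
        t_index = {t: j for j, t in enumerate(terms)}
        pos = y == np.unique(y)[1]
        n = len(token_docs)
        present_pos = np.zeros(len(terms))
        present_neg = np.zeros(len(terms))
        for toks, is_pos in zip(token_docs, pos):
            for t in set(toks):
                j = t_index.get(t)
                if j is None:
                    continue
                if is_pos:
                    present_pos[j] += 1
                else:
                    present_neg[j] += 1
        n_pos, n_neg = int(pos.sum()), int(n - pos.sum())
        h_c = _entropy(np.array([n_pos, n_neg]))

        def h2(a, b):
            tot = a + b
            out = np.zeros_like(a, dtype=float)
            m = tot > 0
            pa = np.where(m, a / np.where(m, tot, 1), 0.0)
            pb = np.where(m, b / np.where(m, tot, 1), 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[m] = -(
                    np.where(pa[m] > 0, pa[m] * np.log2(pa[m]), 0.0)
                    + np.where(pb[m] > 0, pb[m] * np.log2(pb[m]), 0.0)
                )
            return out

        present = present_pos + present_neg
        absent_pos = n_pos - present_pos
        absent_neg = n_neg - present_neg
        ig = h_c - (present / n) * h2(present_pos, present_neg) \
                 - ((n - present) / n) * h2(absent_pos, absent_neg)
        self.feature_set_ = select_top_k(dict(zip(terms, ig)), vocab, self.k)
        self.vocabulary_ = vocab
        self._stop = stop
        return self

    def transform(self, texts) -> sp.csr_matrix:
        fs = self.feature_set_
        index = fs.index
        idf_arr = np.asarray(fs.idf)
        rows, cols, vals = [], [], []
        for i, text in enumerate(texts):
            counts: dict[int, float] = {}
            for tok in tokenize(text, self._stop):
                j = index.get(tok)
                if j is not None:
                    counts[j] = counts.get(j, 0.0) + 1.0
            if not counts:
                continue
            js = np.fromiter(counts.keys(), dtype=int)
            ws = np.fromiter(counts.values(), dtype=float) * idf_arr[js]
            if self.normalize:
                norm = np.linalg.norm(ws)
                if norm > 0:
                    ws = ws / norm
            rows.extend([i] * len(js))
            cols.extend(js.tolist())
            vals.extend(ws.tolist())
        n_texts = len(list(texts)) if not hasattr(texts, "__len__") else len(texts)
        return sp.csr_matrix((vals, (rows, cols)), shape=(n_texts, len(fs.terms)))
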