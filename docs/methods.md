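# Methods

This note documents the models and procedures implemented in `litriage`,
the defaults and why they were chosen, what the synthetic corpora do and
do not emulate, and the numerical choices that affect reproducibility.

## Pipeline model

Triage is a cascade over a category tree.  Level 0 is a binary
curatability decision; Levels 1–3 are category assignments made greedily
top-down, one sibling set at a time.  A wrong turn at one level is never
revisited deeper down — this mirrors the production workflow the design
targets (each level's queue only contains the documents routed to it)
and keeps training local: every classifier sees only documents from its
own sibling set, so negatives are always same-parent siblings.  No
global path optimisation is attempted.

Branches may skip levels.  In the default taxonomy Transplantation and
Cancer have no Level 2 (their configured children, if any, sit directly
at Level 3) and HIV stops at Level 1.  Label tables encode skipped or
inapplicable levels as the literal string `NA`.

## Features

Classification text is the title concatenated with the abstract.
Tokenisation lowercases, splits on non-alphanumerics, drops tokens
shorter than two characters and pure digits, and removes a bundled
PubMed-style stopword list.  These tokenisation details are conventions
of this implementation (configurable via the stopword set); nothing
downstream depends on them beyond determinism.

Per classification task, computed on that task's training documents
only (never on held-out folds):

* rare-word filter: a term must occur in ≥ `min_df` = 3 documents;
* ranking by information gain of term *presence* against the binary
  task label, entropies base 2; the top `k` = 100 terms are kept, ties
  broken lexicographically so selection is a pure function of the data;
* weights TF·IDF with TF = raw in-document count and IDF = ln(N/df).
  Any monotone IDF variant would serve; the natural log is fixed for
  reproducibility.  Document vectors are scaled to unit Euclidean
  length by default (`normalize=True`) so SVM margins are comparable
  across documents of different lengths; the flag is exposed because
  raw counts are occasionally preferable for diagnostics.

Reading "a feature threshold of 100" as *top-100 by IG rank* rather
than an IG value of 100 is forced: information gain is bounded by the
label entropy (≤ 1 bit for binary tasks).

## Base classifiers

The binary learner is a soft-margin linear SVM, objective
½‖w‖² + C·Σ hinge with unregularised bias, solved exactly (libsvm dual
behind a thin estimator).  Defaults C = 1, tolerance 1e-4 — standard for
era-typical text classification; a linear kernel is the norm for sparse
bag-of-words.  Tests verify the solution against a brute-force primal QP
oracle on a small instance with on-margin support vectors (where the
bias is unique).

Every SVM task uses a **leave-one-subset-out ensemble**: a seeded,
label-stratified shuffle splits the training set into m = 10 disjoint
subsets; member i trains on all but subset i; the ensemble margin is the
member mean.  Stratification is this package's choice (the procedure is
otherwise underdetermined): it prevents degenerate single-class members
on imbalanced tasks.  All members share the feature set selected on the
full task training data.  Training an ensemble requires ≥ m examples of
each class.

A multinomial Naive Bayes scorer (Laplace α = 1, log posterior odds) is
included purely as the historical baseline for the curatability
decision; on separable synthetic corpora the SVM ensemble's ranking is
at least as good in the large majority of seeded replicates.

## Combiner and cost sensitivity

Each sibling set's one-vs-rest ensemble scores form a score profile; a
one-hidden-layer perceptron maps profiles to category probabilities.
The hidden width is ⌊n/2⌋ (minimum 2) for n siblings — the "number of
categories divided by two" convention read as hidden *units*; a stack of
n/2 hidden *layers* would be implausible for a 7-input combiner, and the
choice is isolated behind the `hidden_units` parameter.  Sigmoid hidden
units, softmax output, weighted cross-entropy, full-batch gradient
descent with learning rate 0.3 and momentum 0.2 for 500 epochs
(era-typical neural-network defaults), inputs standardised internally,
initial weights drawn from a seeded uniform — training is bit-for-bit
reproducible given the seed.  The combiner trains on *pooled
out-of-fold* score profiles (5-fold by default) so it never sees
profiles produced by ensembles that trained on the same documents.

Cost matrices are square true-by-predicted tables with zero diagonal.
Two canonical constructions:

* **priority matrix** (Level 1): high→low 5, high→other-high 1,
  low→other-low 0.2, low→high 1.  The low→high cost is not pinned by
  any headline constraint; 1 treats it as an ordinary misclassification
  and is consistent with the observed behaviour that borderline
  documents shift toward high priority.  It is fully configurable.
* **catch-all matrix** (Levels 2–3, when an "Other"/"Various" sibling
  exists): specific→catch-all 5, catch-all→specific 0.2,
  specific→specific 1; two catch-alls confused with each other cost
  0.2.

Cost sensitivity acts twice, each independently switchable, because the
underlying mechanism ("trained to minimise total cost") is ambiguous
between the two standard realisations:

* training-time: instance weights = class row-sum / mean row-sum
  (scale-invariant; uniform matrix ⇒ all weights 1);
* decision-time: predicted category = argmin_j Σ_i p_i·C[i,j], ties to
  the smallest canonical index.  With uniform costs this is exactly
  argmax probability.

A practical consequence worth knowing: under the priority matrix a
low-priority category is only predicted when its probability is high
(roughly p > 5/6 against two high-priority alternatives), so on small
or imbalanced corpora low-priority predictions can shrink drastically.
That asymmetry is the design goal, not an artefact — the same behaviour
appears in the full-scale system as a large increase of low→high errors
in exchange for halving high→low losses.

## Level-0 calibration

The curatability threshold is calibrated on pooled out-of-fold
cross-validation scores (10-fold): sweep the midpoints of sorted unique
scores plus ±∞; among cutoffs with sensitivity ≥ target (default 0.95,
the human inter-annotator disagreement rate), take the one maximising
specificity, and among equal-specificity candidates the *highest*
cutoff.  The last tie-break matters: on well-separated data many cutoffs
reach 100% specificity, and choosing the highest keeps the achieved
sensitivity tracking the target (~95%) instead of saturating at 100%,
which is how the full-scale system behaves (95.3% realised against a
95% target).  With few positives the sensitivity constraint forces all
of them above the cutoff and the classic "threshold between the
classes" behaviour re-emerges.  The cross-validation threshold is
reused unchanged for prediction; it is not recalibrated on the full
training set.

If a sibling set has a category with fewer than max(`min_examples`, m)
documents the whole set falls back to majority-class assignment (with a
log warning) rather than training degenerate ensembles; single-child
sets pass through.

## Evaluation machinery

AUC uses the Mann–Whitney rank formulation (tied pairs count ½), which
equals the trapezoidal ROC area; both routes are compared to 1e-12 in
tests.  Cross-validation is stratified (10-fold at Levels 0–1, 5-fold
deeper, per the original protocol; unstratified folds are used with a
warning when a class has fewer members than folds).  The
flat-vs-hierarchical comparison trains each category twice on a shared
fold plan — negatives restricted to siblings vs negatives including all
other curatable documents — and evaluates both on the same within-branch
ranking task, summarised by a classical paired two-sided t-test
(zero-variance differences are an explicit error reported as "no
difference").  Percentages are reported to one decimal where tables are
mirrored; raw fractions are always retained.

## Synthetic corpora

The generator emulates the *structure* the classifiers assume, not real
MEDLINE statistics: a Zipf(1) background vocabulary (2,000 terms) shared
by all documents; a disjoint uniform signal vocabulary of s = 20 terms
per taxonomy node; a generic curatability signal node on every curatable
path and a disjoint "uncuratable" vocabulary for the rest.  A curatable
document of mean length λ = 150 (Poisson) draws each token from the
background with probability α = 0.7, otherwise uniformly from one of its
path's signal nodes.  Uniform (rather than Zipf) signal distributions
keep the information-gain arithmetic of tests tractable.  Class
imbalance defaults: 25% of documents uncuratable; per-leaf quotas are
configurable (`leaf_weights`) to emulate dominant branches.  All
randomness flows from one seed through `numpy` `SeedSequence` spawning,
so any corpus regenerates byte-identically from its manifest.

Two presets deliberately bend the rules to create the regimes the cost
matrices exist for: the *confusable pair* (two Level-1 categories
sharing 90% of their signal terms, α = 0.9, 60 high-priority vs 600
low-priority documents) produces genuine high/low confusion, and the
*catch-all* sibling set gives its "Other" bucket no signal vocabulary at
all (pure background), emulating heterogeneous residual categories.

Because the synthetic vocabularies are cleanly separable, passing
recovery checks demonstrate that the machinery is wired correctly —
feature selection finds the signal terms, ensembles rank categories,
cost matrices move decisions in the designed direction — but say nothing
about absolute performance on real abstracts, where vocabulary overlap,
polysemy and topic drift dominate.  Full-scale corpora for this task are
PMID lists whose text must be fetched; the package reads them (MEDLINE,
PubMed XML or TSV) but does not depend on them for any test.

## Problem sizes

Desk-scale defaults keep every study fast on one core: the Level-1
recovery corpus is ~2,000 documents (Infectious Disease branch
up-weighted ×6 to emulate the dominant branch), directional cost studies
use 320–660 documents, and the end-to-end workflow default is ~1,000
documents — minutes in total.

## Known limitations

* Greedy routing propagates Level-1 errors downward by construction.
* Bag-of-words unigrams only: no stemming, n-grams or embeddings.
* SVM scores feed the combiner as raw margins (no calibration); the
  combiner's softmax probabilities are only as calibrated as its
  cross-entropy training makes them.
* The bias of the exact SVM dual is non-unique when every support
  vector is at bound; downstream code only consumes score *rankings*
  and ensemble means, which are insensitive in practice.
* The default taxonomy ships only published nodes; realistic trees
  (e.g. Infectious Disease sub-branches) must come from user config.
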