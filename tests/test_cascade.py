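"""Level-0 calibration and the hierarchical cascade."""

import numpy as np
import pytest

from litriage import (
    CURATABLE,
    UNCURATABLE,
    HierarchicalTriageClassifier,
    NA,
    calibrate_level0_threshold,
    classify_corpus,
    results_to_frame,
)
from litriage.cascade import TriageResult


def exhaustive_calibration_oracle(scores, labels, target):
    """Evaluate every candidate cutoff directly (independent of the sweep)."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    uniq = np.unique(scores)
    cuts = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    feasible = []
    for cut in cuts:
        called = scores >= cut
        sens = (called & y).sum() / y.sum()
        spec = (~called & ~y).sum() / (~y).sum()
        if sens >= target:
            feasible.append((spec, cut))
    if not feasible:
        return None
    return max(feasible)[1]


class TestCalibration:
    def test_perfectly_separated_small_set(self):
        scores = [-3, -2, -1, 1, 2, 3]
        labels = [0, 0, 0, 1, 1, 1]
        cut, stats = calibrate_level0_threshold(scores, labels, 0.95)
        assert -1 < cut < 1
        assert stats == {"sensitivity": 1.0, "specificity": 1.0}

    def test_zero_target_maximizes_specificity_alone(self):
        cut, stats = calibrate_level0_threshold([0, 1, 2, 3], [0, 1, 0, 1], 0.0)
        assert stats["specificity"] == 1.0

    def test_matches_exhaustive_cutoff_oracle(self):
        scores = [0.1, 0.15, 0.3, 0.35, 0.4, 0.6, 0.7, 0.9]
        labels = [0, 0, 1, 0, 1, 1, 0, 1]
        for target in (0.0, 0.5, 0.75, 1.0):
            cut, _ = calibrate_level0_threshold(scores, labels, target)
            assert cut == exhaustive_calibration_oracle(scores, labels, target)

    def test_constraint_binds_on_large_separable_set(self, rng):
        # with many positives the best-specificity feasible cutoff sits at
        # the target quantile of the positive scores, not below them all
        scores = np.concatenate([rng.normal(-2, 0.5, 300), rng.normal(2, 0.5, 300)])
        labels = np.array([0] * 300 + [1] * 300)
        cut, stats = calibrate_level0_threshold(scores, labels, 0.95)
        assert 0.94 <= stats["sensitivity"] <= 0.97
        assert stats["specificity"] == 1.0

    def test_impossible_target_accepts_everything(self):
        # tied scores: the only cutoff reaching 99.9% sensitivity accepts all
        cut, stats = calibrate_level0_threshold([1, 1, 1, 1], [0, 0, 1, 1], 0.999)
        assert cut == -np.inf
        assert stats == {"sensitivity": 1.0, "specificity": 0.0}

    def test_raising_threshold_shrinks_curatable_set(self, rng):
        scores = rng.normal(size=200)
        for lo, hi in [(-1.0, 0.0), (0.0, 0.5), (0.5, 1.5)]:
            assert (scores >= hi).sum() <= (scores >= lo).sum()


class TestHierarchyTraining:
    def test_trained_sibling_sets_match_tree_walk(self, trained_model, small_taxonomy):
        trainable = {p for p, kids in small_taxonomy.sibling_sets() if len(kids) >= 2}
        modeled = {p for p, n in trained_model.node_models_.items() if n.mode == "model"}
        assert modeled == trainable

    def test_one_vs_rest_negatives_are_siblings_only(self, trained_model, small_corpus):
        # the sibling-set classifiers under SubA2 were trained on exactly
        # the SubA2 documents: positives + sibling negatives = set size
        _, labels = small_corpus
        set_docs = [l for l in labels if l.level2 == "SubA2"]
        node = trained_model.node_models_["SubA2"]
        ens = node.ensembles["LeafX"]
        n_trained = sum(len(s) for s in ens.subsets_)
        assert n_trained == len(set_docs)
        n_pos = sum(1 for l in set_docs if l.level3 == "LeafX")
        assert n_pos == 30  # docs_per_leaf; negatives are the 60 siblings

    def test_single_child_passes_through(self, small_corpus):
        import litriage
        tax = litriage.load_taxonomy({"level1": [
            {"name": "A", "priority": "high", "children": [{"name": "OnlyChild"}]},
            {"name": "B", "priority": "low"},
        ]})
        from litriage.synthetic import GeneratorConfig, generate_corpus
        abstracts, labels = generate_corpus(tax, GeneratorConfig(seed=5, docs_per_leaf=25))
        model = HierarchicalTriageClassifier(taxonomy=tax, random_state=0)
        model.fit(abstracts, labels)
        assert model.node_models_["A"].mode == "passthrough"
        rec = next(a for a, l in zip(abstracts, labels) if l.level1 == "A")
        res = model.predict_one(rec)
        if res.level1 == "A":
            assert res.level2 == "OnlyChild"

    def test_starved_sibling_set_falls_back_to_majority(self, small_taxonomy):
        from litriage.synthetic import GeneratorConfig, generate_corpus
        cfg = GeneratorConfig(seed=9, docs_per_leaf=30,
                              leaf_weights={"LeafY": 0.1})  # 3 docs < m
        abstracts, labels = generate_corpus(small_taxonomy, cfg)
        model = HierarchicalTriageClassifier(taxonomy=small_taxonomy, random_state=0)
        model.fit(abstracts, labels)
        node = model.node_models_["SubA2"]
        assert node.mode == "majority"
        assert node.majority_class in ("LeafX", "OTHZ")


class TestClassification:
    def test_uncuratable_documents_stop_at_level0(self, trained_model, small_corpus):
        abstracts, labels = small_corpus
        results = trained_model.predict(abstracts)
        for res in results:
            if res.level0_call == UNCURATABLE:
                assert res.path == (NA, NA, NA)

    def test_skip_branch_gets_na_deeper_levels(self, trained_model, small_corpus):
        abstracts, labels = small_corpus
        results = trained_model.predict(abstracts)
        routed = [r for r in results if r.level1 == "LowC"]
        assert routed, "no documents routed to the skip branch"
        assert all(r.level2 == NA and r.level3 == NA for r in routed)

    def test_every_path_is_taxonomy_consistent(self, trained_model, small_corpus,
                                               small_taxonomy):
        abstracts, _ = small_corpus
        for res in trained_model.predict(abstracts):
            if res.level0_call == CURATABLE:
                small_taxonomy.validate_path(res.level1, res.level2, res.level3)

    def test_corpus_summary_counts_conserved(self, trained_model, small_corpus):
        abstracts, _ = small_corpus
        results, summary = classify_corpus(trained_model, abstracts)
        assert summary["n_documents"] == len(abstracts)
        for level in ("level1", "level2", "level3"):
            assert sum(summary[level].values()) == len(abstracts)
        assert sum(summary["level0"].values()) == len(abstracts)

    def test_empty_corpus(self, trained_model):
        results, summary = classify_corpus(trained_model, [])
        assert results == [] and summary["n_documents"] == 0

    def test_rerun_is_deterministic(self, trained_model, small_corpus):
        abstracts, _ = small_corpus
        a = trained_model.predict(abstracts[:40])
        b = trained_model.predict(abstracts[:40])
        assert [r.path for r in a] == [r.path for r in b]
        assert [r.level0_score for r in a] == [r.level0_score for r in b]

    def test_results_table_shape(self, trained_model, small_corpus):
        abstracts, _ = small_corpus
        frame = results_to_frame(trained_model.predict(abstracts[:10]))
        assert list(frame.columns) == ["pmid", "level0_score", "level0_call",
                                       "level1", "level2", "level3", "basis"]
        assert len(frame) == 10


class TestBundle:
    def test_json_roundtrip_preserves_predictions(self, trained_model, small_corpus,
                                                  tmp_path):
        abstracts, _ = small_corpus
        path = tmp_path / "model.json"
        trained_model.save(path)
        loaded = HierarchicalTriageClassifier.load(path)
        a = trained_model.predict(abstracts[:30])
        b = loaded.predict(abstracts[:30])
        assert [r.path for r in a] == [r.path for r in b]
        np.testing.assert_allclose([r.level0_score for r in a],
                                   [r.level0_score for r in b], atol=1e-12)

    def test_bundle_refuses_foreign_payload(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="bundle"):
            HierarchicalTriageClassifier.load(path)
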