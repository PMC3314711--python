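import numpy as np
import pytest

from litriage import GeneratorConfig, HierarchicalTriageClassifier, load_taxonomy
from litriage.synthetic import generate_corpus


@pytest.fixture(scope="session")
def small_taxonomy():
    """Three-level tree with skip rules and catch-all flags exercised."""
    return load_taxonomy({"level1": [
        {"name": "InfA", "priority": "high", "children": [
            {"name": "SubA1"},
            {"name": "SubA2", "children": [
                {"name": "LeafX"},
                {"name": "LeafY"},
                {"name": "OTHZ", "catch_all": True},
            ]},
        ]},
        {"name": "AutoB", "priority": "high", "children": [
            {"name": "SubB1"}, {"name": "SubB2"},
        ]},
        {"name": "LowC", "priority": "low", "skip_levels": [2, 3]},
    ]})


@pytest.fixture(scope="session")
def small_corpus(small_taxonomy):
    # the skip branch gets a triple quota so the low-priority class stays
    # visible under the cost-sensitive decision rule
    cfg = GeneratorConfig(seed=7, docs_per_leaf=30, leaf_weights={"LowC": 3.0})
    return generate_corpus(small_taxonomy, cfg)


@pytest.fixture(scope="session")
def trained_model(small_taxonomy, small_corpus):
    abstracts, labels = small_corpus
    model = HierarchicalTriageClassifier(taxonomy=small_taxonomy, random_state=3)
    return model.fit(abstracts, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
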