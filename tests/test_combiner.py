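"""Cost matrices, instance weights, the MLP combiner and min-cost decisions."""

import itertools

import numpy as np
import pytest

from litriage.combiner import (
    CostMatrix,
    CostSensitiveMLP,
    build_catchall_cost_matrix,
    build_priority_cost_matrix,
    instance_weights,
    min_expected_cost_decision,
    predict_probs,
    uniform_cost_matrix,
)
from litriage.taxonomy import PriorityPartition, default_taxonomy

PARTITION = PriorityPartition(
    high=("Allergy", "Autoimmunity", "Infectious Disease", "Transplantation"),
    low=("Cancer", "HIV", "Other"),
)


class TestPriorityCostMatrix:
    def test_default_entries_by_exhaustive_enumeration(self):
        cm = build_priority_cost_matrix(PARTITION)
        assert set(np.unique(cm.matrix)) == {0.0, 0.2, 1.0, 5.0}
        for true, pred in itertools.product(cm.categories, repeat=2):
            if true == pred:
                expected = 0.0
            else:
                t, p = PARTITION.priority_of(true), PARTITION.priority_of(pred)
                expected = {("high", "high"): 1.0, ("high", "low"): 5.0,
                            ("low", "high"): 1.0, ("low", "low"): 0.2}[(t, p)]
            assert cm.cost(true, pred) == expected
        # 4 high categories x 3 low columns cost 5
        assert (cm.matrix == 5.0).sum() == 12

    def test_all_high_partition_collapses_to_uniform(self):
        part = PriorityPartition(high=("A", "B", "C"), low=())
        cm = build_priority_cost_matrix(part)
        np.testing.assert_array_equal(cm.matrix, 1.0 - np.eye(3))

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            build_priority_cost_matrix(PARTITION, c_hl=-1.0)


class TestCatchallCostMatrix:
    def test_diabetes_sibling_matrix_by_enumeration(self):
        tax = default_taxonomy()
        sibs = tax.children("Diabetes")
        flags = tax.catch_all_flags("Diabetes")
        cm = build_catchall_cost_matrix(sibs, flags)
        assert cm.cost("GAD", "OTH") == 5.0
        assert cm.cost("OTH", "GAD") == 0.2
        for true, pred in itertools.product(sibs, repeat=2):
            if true == pred:
                expected = 0.0
            elif flags[pred]:
                expected = 0.2 if flags[true] else 5.0
            elif flags[true]:
                expected = 0.2
            else:
                expected = 1.0
            assert cm.cost(true, pred) == expected

    def test_minimal_two_by_two(self):
        cm = build_catchall_cost_matrix(["Spec", "Other"], {"Other": True})
        np.testing.assert_array_equal(cm.matrix, [[0.0, 5.0], [0.2, 0.0]])

    def test_no_catchall_flag_directs_to_uniform(self):
        with pytest.raises(ValueError, match="uniform"):
            build_catchall_cost_matrix(["A", "B"], {})


class TestCostMatrixValidation:
    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            CostMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CostMatrix(("a", "b", "c"), np.zeros((2, 2)))


class TestInstanceWeights:
    def test_uniform_matrix_gives_unit_weights(self):
        cm = uniform_cost_matrix(["a", "b", "c"])
        np.testing.assert_allclose(instance_weights(["a", "b", "c", "a"], cm), 1.0)

    def test_high_priority_rows_weigh_more(self):
        cm = build_priority_cost_matrix(PARTITION)
        w = instance_weights(list(cm.categories), cm)
        by_cat = dict(zip(cm.categories, w))
        # row-sum arithmetic: high rows = 3*1 + 3*5 = 18, low = 4*1 + 2*0.2 = 4.4
        mean = (4 * 18 + 3 * 4.4) / 7
        assert by_cat["Allergy"] == pytest.approx(18 / mean)
        assert by_cat["Cancer"] == pytest.approx(4.4 / mean)
        assert all(by_cat[h] > by_cat[l] for h in PARTITION.high for l in PARTITION.low)

    def test_invariant_to_positive_scaling(self):
        cm = build_priority_cost_matrix(PARTITION)
        scaled = CostMatrix(cm.categories, cm.matrix * 7.5)
        labels = list(cm.categories) * 2
        np.testing.assert_allclose(
            instance_weights(labels, cm), instance_weights(labels, scaled)
        )

    def test_zero_matrix_rejected(self):
        cm = CostMatrix(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            instance_weights(["a"], cm)


class TestMinExpectedCostDecision:
    def test_uniform_costs_reduce_to_argmax(self, rng):
        cm = uniform_cost_matrix([f"c{i}" for i in range(5)])
        for _ in range(50):
            p = rng.dirichlet(np.ones(5))
            assert min_expected_cost_decision(p, cm) == int(np.argmax(p))

    def test_certain_probability_returns_that_class(self):
        cm = build_priority_cost_matrix(PARTITION)
        for i in range(cm.n):
            p = np.zeros(cm.n)
            p[i] = 1.0
            assert min_expected_cost_decision(p, cm) == i

    def test_uniform_probs_prefer_high_priority_by_column_sums(self):
        cm = build_priority_cost_matrix(PARTITION)
        p = np.full(7, 1 / 7)
        # brute-force column sums
        sums = [sum(p[i] * cm.matrix[i, j] for i in range(7)) for j in range(7)]
        j = min(range(7), key=lambda j: (sums[j], j))
        assert min_expected_cost_decision(p, cm) == j
        assert PARTITION.priority_of(cm.categories[j]) == "high"

    def test_scaling_invariance_and_tie_break(self):
        cm = build_priority_cost_matrix(PARTITION)
        scaled = CostMatrix(cm.categories, cm.matrix * 100)
        p = np.full(7, 1 / 7)
        assert min_expected_cost_decision(p, cm) == min_expected_cost_decision(p, scaled)
        # exact tie between identical columns resolves to the smaller index
        tie = CostMatrix(("a", "b", "c"), 1.0 - np.eye(3))
        assert min_expected_cost_decision([1 / 3, 1 / 3, 1 / 3], tie) == 0


class TestMLP:
    def _profiles(self, rng, n=120, n_classes=3):
        y = rng.integers(0, n_classes, n)
        X = rng.normal(0, 0.3, (n, n_classes))
        X[np.arange(n), y] += 2.0
        return X, np.array([f"c{i}" for i in y])

    def test_default_hidden_width_is_half_the_categories(self):
        X = np.tile(np.eye(7), (20, 1))
        y = np.array([f"c{i}" for i in range(7)] * 20)
        mlp = CostSensitiveMLP(epochs=1).fit(X, y)
        assert mlp.W1_.shape == (7, 3)

    def test_separable_profiles_learned_to_high_accuracy(self, rng):
        X, y = self._profiles(rng)
        mlp = CostSensitiveMLP(random_state=0).fit(X, y)
        assert (mlp.predict(X) == y).mean() >= 0.99

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(6, 3))
        Y = np.eye(3)[rng.integers(0, 3, 6)]
        w = rng.uniform(0.5, 2.0, 6)
        params = [rng.normal(scale=0.5, size=s)
                  for s in [(3, 2), (2,), (2, 3), (3,)]]
        _, grads = CostSensitiveMLP.loss_and_grads(params, X, Y, w)
        eps = 1e-6
        for p, g in zip(params, grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = CostSensitiveMLP.loss_and_grads(params, X, Y, w)
                p[idx] = orig - eps
                lm, _ = CostSensitiveMLP.loss_and_grads(params, X, Y, w)
                p[idx] = orig
                assert g[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)

    def test_probabilities_normalised_and_deterministic(self, rng):
        X, y = self._profiles(rng)
        mlp = CostSensitiveMLP(random_state=7).fit(X, y)
        q = rng.normal(size=(10, 3))
        p = mlp.predict_proba(q)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        mlp2 = CostSensitiveMLP(random_state=7).fit(X, y)
        np.testing.assert_array_equal(p, mlp2.predict_proba(q))

    def test_zero_weights_give_uniform_output(self):
        mlp = CostSensitiveMLP()
        mlp.W1_ = np.zeros((4, 2)); mlp.b1_ = np.zeros(2)
        mlp.W2_ = np.zeros((2, 4)); mlp.b2_ = np.zeros(4)
        mlp.mean_ = np.zeros(4); mlp.scale_ = np.ones(4)
        mlp.classes_ = np.array(list("abcd"))
        np.testing.assert_allclose(predict_probs(mlp, np.zeros(4)), 0.25)

    def test_profile_length_mismatch_rejected(self, rng):
        X, y = self._profiles(rng)
        mlp = CostSensitiveMLP(epochs=5).fit(X, y)
        with pytest.raises(ValueError, match="length"):
            mlp.predict_proba(np.zeros((1, 9)))

    @pytest.mark.parametrize("bad", [{"epochs": 0}, {"hidden_units": 0}])
    def test_invalid_hyperparameters_rejected(self, rng, bad):
        X, y = self._profiles(rng)
        with pytest.raises(ValueError):
            CostSensitiveMLP(**bad).fit(X, y)
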