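"""SVM, leave-one-subset-out ensemble, and Naive Bayes base learners."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from litriage.classifiers import (
    LinearSVM,
    MultinomialNBScorer,
    SvmEnsemble,
    decision_score,
    ensemble_score,
    train_ensemble,
    train_linear_svm,
)


def primal_qp_oracle(X, y, C):
    """Brute-force soft-margin primal: min 0.5||w||^2 + C sum(xi) via SLSQP.

    Variables are (w, b, xi); constraints xi >= 0 and y(w.x+b) >= 1-xi.
    Independent of the package's solver path.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape

    def unpack(z):
        return z[:d], z[d], z[d + 1:]

    def obj(z):
        w, _, xi = unpack(z)
        return 0.5 * w @ w + C * xi.sum()

    cons = [
        {"type": "ineq", "fun": lambda z, i=i: unpack(z)[2][i]} for i in range(n)
    ] + [
        {"type": "ineq",
         "fun": lambda z, i=i: y[i] * (X[i] @ unpack(z)[0] + unpack(z)[1]) - 1 + unpack(z)[2][i]}
        for i in range(n)
    ]
    res = minimize(obj, np.zeros(d + 1 + n), constraints=cons,
                   method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14})
    assert res.success
    w, b, _ = unpack(res.x)
    return w, b


class TestLinearSVM:
    def test_separable_case_perfect_ranking(self):
        X = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        y = [0, 0, 1, 1]
        model = train_linear_svm(X, y, C=100.0)
        s = model.decision_function(X)
        assert (s[:2] < 0).all() and (s[2:] > 0).all()

    def test_label_flip_negates_scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=30) > 0).astype(int)
        s1 = LinearSVM(C=1.0, tol=1e-8).fit(X, y).decision_function(X)
        s2 = LinearSVM(C=1.0, tol=1e-8).fit(X, 1 - y).decision_function(X)
        np.testing.assert_allclose(s1, -s2, atol=1e-4)

    @pytest.mark.parametrize("C", [0.5, 1.0, 10.0])
    def test_matches_brute_force_qp(self, C):
        # 4-point 2-D instance with on-margin support vectors (unique bias)
        X = np.array([[0.5, 1.9], [-0.6, 1.8], [-0.1, 0.3], [1.5, 0.2]])
        y01 = np.array([0, 0, 1, 1])
        w, b = primal_qp_oracle(X, np.where(y01 == 1, 1.0, -1.0), C)
        model = LinearSVM(C=C, tol=1e-8).fit(X, y01)
        np.testing.assert_allclose(
            model.decision_function(X), X @ w + b, atol=1e-4
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            LinearSVM().fit(np.eye(3), [1, 1, 1])

    def test_duplication_invariance(self):
        # duplicating every document doubles the hinge term, so halving C
        # on the duplicated set recovers the same solution
        X = np.array([[0.5, 1.9], [-0.6, 1.8], [-0.1, 0.3], [1.5, 0.2]])
        y = np.array([0, 0, 1, 1])
        base = LinearSVM(C=1.0, tol=1e-8).fit(X, y)
        dup = LinearSVM(C=0.5, tol=1e-8).fit(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(base.coef_, dup.coef_, atol=1e-5)
        assert base.intercept_ == pytest.approx(dup.intercept_, abs=1e-5)


class TestDecisionScore:
    def _model(self):
        return LinearSVM.from_weights([0.5, -1.0, 2.0], 0.25)

    def test_zero_vector_returns_bias(self):
        assert decision_score(self._model(), np.zeros(3)) == pytest.approx(0.25)

    def test_linearity(self):
        m = self._model()
        x, z = np.array([1.0, 2.0, 3.0]), np.array([-1.0, 0.5, 0.0])
        assert decision_score(m, x + z) == pytest.approx(
            decision_score(m, x) + decision_score(m, z) - m.intercept_
        )

    def test_explicit_dot_product(self):
        assert decision_score(self._model(), [2.0, 1.0, 0.5]) == \
            pytest.approx(0.5 * 2 - 1.0 * 1 + 2.0 * 0.5 + 0.25)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            decision_score(self._model(), np.zeros(5))


class TestEnsemble:
    def _data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        y = (X[:, 0] > 0).astype(int)
        return X, y

    def test_default_ensemble_has_ten_members(self):
        X, y = self._data()
        ens = train_ensemble(X, y, seed=1)
        assert len(ens.members_) == 10

    def test_subsets_partition_the_training_set(self):
        X, y = self._data()
        ens = SvmEnsemble(m=5, random_state=2).fit(X, y)
        all_idx = np.concatenate(ens.subsets_)
        assert len(all_idx) == len(y)
        assert len(np.unique(all_idx)) == len(y)

    def test_stratified_members_see_both_classes(self):
        X, y = self._data()
        ens = SvmEnsemble(m=10, random_state=0).fit(X, y)
        for held_out in ens.subsets_:
            keep = np.setdiff1d(np.arange(len(y)), held_out)
            assert len(np.unique(y[keep])) == 2

    def test_score_is_mean_of_member_scores(self, rng):
        X, y = self._data()
        ens = SvmEnsemble(m=4, random_state=0).fit(X, y)
        q = rng.normal(size=(7, 5))
        member_scores = np.stack([m.decision_function(q) for m in ens.members_])
        np.testing.assert_allclose(ens.decision_function(q), member_scores.mean(axis=0))

    def test_identical_members_collapse_to_member_score(self):
        # duplicated data make every leave-one-subset-out training set identical
        X = np.array([[1.0], [-1.0]] * 20)
        y = np.array([1, 0] * 20)
        ens = SvmEnsemble(m=4, random_state=0).fit(X, y)
        q = np.array([[0.3]])
        assert ensemble_score(ens, q[0]) == pytest.approx(
            float(ens.members_[0].decision_function(q)[0])
        )

    def test_too_few_examples_rejected(self):
        X = np.vstack([np.ones((3, 2)), -np.ones((20, 2))])
        y = np.array([1] * 3 + [0] * 20)
        with pytest.raises(ValueError, match="at least m"):
            SvmEnsemble(m=10).fit(X, y)

    def test_score_invariant_to_member_order(self, rng):
        X, y = self._data()
        ens = SvmEnsemble(m=4, random_state=0).fit(X, y)
        q = rng.normal(size=(3, 5))
        before = ens.decision_function(q)
        ens.members_ = ens.members_[::-1]
        np.testing.assert_allclose(ens.decision_function(q), before)


class TestSvmVsNaiveBayes:
    def test_ensemble_ranking_not_worse_on_separable_corpora(self):
        """On cleanly separable synthetic text the SVM ensemble's held-out
        ranking matches or beats the Naive Bayes baseline in >= 80% of seeds.

        Both learners saturate near AUC 1.0 here; the check guards against a
        wiring regression that would break the ensemble's ranking, not a
        performance gap (which only appears on overlapping vocabularies).
        """
        import scipy.sparse as sp

        from litriage.evaluation import roc_auc
        from litriage.features import TfidfIgVectorizer, load_stopwords, tokenize
        from litriage.synthetic import confusable_pair_corpus

        stop = load_stopwords()
        wins = 0
        for seed in range(5):
            texts, y, _ = confusable_pair_corpus(
                seed, n_high=100, n_low=100, shared_fraction=0.0, alpha=0.7
            )
            yb = (y == "HighDisease").astype(int)
            order = np.random.default_rng(seed).permutation(len(yb))
            tr, te = order[:130], order[130:]
            ttr = [texts[i] for i in tr]
            tte = [texts[i] for i in te]
            vec = TfidfIgVectorizer(k=100).fit(ttr, yb[tr])
            svm_auc = roc_auc(
                SvmEnsemble(random_state=seed)
                .fit(vec.transform(ttr), yb[tr])
                .decision_function(vec.transform(tte)),
                yb[te],
            ).auc
            index = vec.feature_set_.index

            def count_matrix(docs):
                M = np.zeros((len(docs), len(index)))
                for i, text in enumerate(docs):
                    for tok in tokenize(text, stop):
                        j = index.get(tok)
                        if j is not None:
                            M[i, j] += 1
                return sp.csr_matrix(M)

            nb_auc = roc_auc(
                MultinomialNBScorer()
                .fit(count_matrix(ttr), yb[tr])
                .decision_function(count_matrix(tte)),
                yb[te],
            ).auc
            wins += svm_auc >= nb_auc
        assert wins >= 4


class TestNaiveBayes:
    def test_empty_document_scores_log_prior_odds(self):
        X = np.array([[2, 0], [3, 1], [0, 2]])
        y = np.array([1, 1, 0])
        nb = MultinomialNBScorer(alpha=1.0).fit(X, y)
        assert nb.decision_function(np.zeros((1, 2)))[0] == \
            pytest.approx(math.log(2 / 3) - math.log(1 / 3))

    def test_symmetric_corpus_balanced_query_scores_zero(self):
        X = np.array([[3, 0], [0, 3]])
        y = np.array([0, 1])
        nb = MultinomialNBScorer().fit(X, y)
        assert nb.decision_function(np.array([[2, 2]]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_posterior(self):
        # 4 docs over 2 terms; class 1: counts (3,1); class 0: counts (1,4).
        # Laplace alpha=1: P(t|c) = (count+1)/(total+2).
        X = np.array([[2, 0], [1, 1], [1, 2], [0, 2]])
        y = np.array([1, 1, 0, 0])
        nb = MultinomialNBScorer(alpha=1.0).fit(X, y)
        p_t1_pos, p_t2_pos = 4 / 6, 2 / 6
        p_t1_neg, p_t2_neg = 2 / 7, 5 / 7
        query = np.array([[3, 1]])
        expected = (3 * math.log(p_t1_pos) + 1 * math.log(p_t2_pos)) \
            - (3 * math.log(p_t1_neg) + 1 * math.log(p_t2_neg))  # priors equal
        assert nb.decision_function(query)[0] == pytest.approx(expected, abs=1e-9)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            MultinomialNBScorer(alpha=0.0).fit(np.eye(2), [0, 1])
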