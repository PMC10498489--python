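"""Classifier zoo, conformal machinery, and consensus rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from oxsar import model_zoo as mz


class TestFitClassifier:
    @pytest.mark.parametrize("algorithm", ["random-forest", "support-vector", "decision-tree"])
    def test_separable_toy_perfect_training_accuracy(self, toy_separable, algorithm):
        X, y = toy_separable
        model = mz.fit_classifier(X, y, algorithm, "physchem", seed=0)
        assert np.array_equal(model.predict(X), y.astype(bool))

    def test_randomized_baseline_has_no_skill(self, toy_separable):
        """Permutation null: held-out MCC of the shuffled-descriptor model ~ 0."""
        rng = np.random.default_rng(0)
        mccs = []
        for rep in range(50):
            X = rng.normal(size=(120, 4))
            y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)  # learnable signal
            tr = rng.permutation(120)[:80]
            te = np.setdiff1d(np.arange(120), tr)
            model = mz.fit_classifier(
                X[tr], y[tr], "randomized-baseline", "randomized", seed=rep
            )
            mccs.append(matthews_corrcoef(y[te], model.predict(X[te])))
        assert np.abs(np.mean(mccs)) <= 0.15
        assert np.percentile(np.abs(mccs), 90) <= 0.35

    def test_determinism(self, toy_separable):
        X, y = toy_separable
        a = mz.fit_classifier(X, y, "random-forest", "physchem", seed=5)
        b = mz.fit_classifier(X, y, "random-forest", "physchem", seed=5)
        assert np.array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            mz.fit_classifier(np.ones((5, 2)), np.zeros(5), "random-forest")

    @pytest.mark.parametrize(
        "algorithm", ["balanced-random-forest", "naive-bayes", "knn-1", "knn-3", "pls",
                      "logistic", "gradient-boosted-trees"]
    )
    def test_all_algorithms_fit_and_predict(self, toy_separable, algorithm):
        X, y = toy_separable
        model = mz.fit_classifier(X, y, algorithm, "physchem", seed=0)
        proba = model.predict_proba(X)
        assert proba.shape == (len(X),)
        assert np.all((proba >= 0) & (proba <= 1))
        assert (model.predict(X) == y.astype(bool)).mean() >= 0.9


class TestBalancedRandomForest:
    def test_recovers_minority_on_imbalanced_data(self):
        rng = np.random.default_rng(1)
        X0 = rng.normal(-1.0, 1.0, size=(270, 3))
        X1 = rng.normal(1.0, 1.0, size=(30, 3))
        X = np.vstack([X0, X1])
        y = np.array([0] * 270 + [1] * 30)
        brf = mz.BalancedRandomForest(n_estimators=100, random_state=0).fit(X, y)
        Xt = rng.normal(1.0, 1.0, size=(100, 3))
        # balanced bootstraps give reasonable sensitivity to the minority class
        assert (brf.predict(Xt) == 1).mean() >= 0.7


class TestConformalPvalue:
    def test_counting_definition(self):
        assert mz.conformal_pvalue(0.25, [0.1, 0.2, 0.3]) == 0.5

    def test_alpha_above_all_scores(self):
        assert mz.conformal_pvalue(0.9, [0.1, 0.2, 0.3]) == 0.25

    def test_alpha_below_all_scores(self):
        assert mz.conformal_pvalue(0.05, [0.1, 0.2, 0.3]) == 1.0

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            mz.conformal_pvalue(0.5, [])


class TestPredictionSet:
    def test_singleton_active(self):
        ps = mz.prediction_set(0.40, 0.10, eps=0.25)
        assert ps.labels == {"active"} and ps.in_ad

    def test_both_classes(self):
        ps = mz.prediction_set(0.40, 0.40, eps=0.25)
        assert ps.labels == {"active", "inactive"} and not ps.in_ad

    def test_empty_set(self):
        ps = mz.prediction_set(0.10, 0.20, eps=0.25)
        assert ps.labels == frozenset() and not ps.in_ad


class TestConformalValidity:
    def test_class_conditional_error_bounded(self):
        """Mondrian validity on a synthetic task (single-seed smoke version)."""
        rng = np.random.default_rng(7)
        n = 1200
        X = rng.normal(size=(n, 5))
        logit = 1.5 * X[:, 0] - X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        tr = np.arange(800)
        te = np.arange(800, n)
        mcp = mz.MondrianConformalClassifier("random-forest", significance=0.25, seed=0).fit(X[tr], y[tr])
        sets = mcp.predict_sets(X[te])
        for cls, name in ((1, "active"), (0, "inactive")):
            mask = y[te] == cls
            err = np.mean([name not in s.labels for s, m in zip(sets, mask) if m])
            sigma = np.sqrt(0.25 * 0.75 / mask.sum())
            assert err <= 0.25 + 3 * sigma

    def test_pvalues_superuniform_for_true_class(self):
        rng = np.random.default_rng(8)
        n = 1000
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + rng.normal(scale=1.0, size=n) > 0).astype(int)
        mcp = mz.MondrianConformalClassifier("random-forest", seed=1).fit(X[:700], y[:700])
        pv = mcp.pvalues(X[700:])
        p_true = np.where(y[700:] == 1, pv[:, 1], pv[:, 0])
        # empirical CDF below the diagonal up to Monte-Carlo noise
        grid = np.linspace(0.05, 0.95, 10)
        ecdf = np.array([(p_true <= g).mean() for g in grid])
        assert np.all(ecdf <= grid + 3 * np.sqrt(grid * (1 - grid) / len(p_true)))


class TestConsensusRules:
    def test_five_of_six_active(self):
        assert mz.majority_vote(["A", "A", "A", "A", "A", "I"], quorum=5) == "A"

    def test_four_two_suspicious(self):
        assert mz.majority_vote(["A", "A", "A", "A", "I", "I"], quorum=5) == "suspicious"

    def test_unanimous_inactive(self):
        assert mz.majority_vote(["I"] * 6, quorum=5) == "I"

    def test_quorum_exceeding_members_rejected(self):
        with pytest.raises(ValueError):
            mz.majority_vote(["A"], quorum=2)

    def test_five_of_six_brute_force(self):
        """Exhaustive check of the 5-of-6 rule over all 64 label vectors."""
        for bits in itertools.product([0, 1], repeat=6):
            labels = ["active" if b else "inactive" for b in bits]
            got = mz.majority_vote(labels, quorum=5)
            n_act = sum(bits)
            expected = "active" if n_act >= 5 else "inactive" if n_act <= 1 else "suspicious"
            assert got == expected

    def test_majority_vote_matches_simple_majority_for_odd_n(self):
        for n in (3, 5, 7):
            quorum = n // 2 + 1
            for bits in itertools.product([0, 1], repeat=n):
                labels = ["active" if b else "inactive" for b in bits]
                assert mz.majority_vote(labels, quorum) == mz.simple_majority(labels)

    def test_simple_majority_tie_is_active(self):
        assert mz.simple_majority(["active"] * 5 + ["inactive"] * 5) == "active"

    def test_simple_majority_counts(self):
        assert mz.simple_majority(["active"] * 7 + ["inactive"] * 4) == "active"
        assert mz.simple_majority(["active"] * 2 + ["inactive"] * 9) == "inactive"


class TestProbabilityEnsemble:
    def test_mean_and_median(self):
        assert mz.probability_ensemble([0.2, 0.4, 0.9], "mean") == pytest.approx(0.5)
        assert mz.probability_ensemble([0.2, 0.4, 0.9], "median") == pytest.approx(0.4)

    def test_idempotent_on_equal_inputs(self):
        assert mz.probability_ensemble([0.7, 0.7, 0.7], "mean") == pytest.approx(0.7)
        assert mz.probability_ensemble([0.7, 0.7, 0.7], "median") == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mz.probability_ensemble([], "mean")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12), st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_mean_permutation_invariant(self, probas, rnd):
        shuffled = probas.copy()
        rnd.shuffle(shuffled)
        assert mz.probability_ensemble(shuffled, "mean") == pytest.approx(
            mz.probability_ensemble(probas, "mean"), nan_ok=False
        )
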