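"""Balanced accuracy, SMOTE, CV evaluation, RFE, MCTS search and evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lrrksig as L
from lrrksig.config import MCTSConfig
from lrrksig.errors import ConfigError
from lrrksig.signature import (DEFAULT_SPEC, STOP, SubsetEvaluator,
                               mcts_feature_search, refine_signature)
from conftest import three_class_problem


class TestBalancedAccuracy:
    def test_perfect_and_partial(self):
        y = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        assert L.balanced_accuracy(y, y) == 1.0
        pred = ["a"] * 4 + ["b"] * 4 + ["a"] * 4  # class c fully wrong
        assert L.balanced_accuracy(y, pred) == pytest.approx(2 / 3)

    def test_majority_predictor_on_imbalanced_classes(self):
        y = ["a"] * 10 + ["b"] * 5 + ["c"] * 5
        pred = ["a"] * 20
        assert L.balanced_accuracy(y, pred) == pytest.approx(1 / 3)

    def test_matches_sklearn(self):
        from sklearn.metrics import balanced_accuracy_score
        rng = np.random.default_rng(0)
        y = rng.integers(0, 4, 200)
        pred = rng.integers(0, 4, 200)
        assert L.balanced_accuracy(y, pred) == pytest.approx(
            balanced_accuracy_score(y, pred))

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            L.balanced_accuracy([], [])


class TestSMOTE:
    def test_balanced_input_unchanged(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        y = np.array([0, 0, 0, 1, 1, 1])
        Xo, yo, prov = L.smote_oversample(X, y, k=1, seed=0)
        np.testing.assert_array_equal(Xo, X)
        np.testing.assert_array_equal(yo, y)
        assert (prov >= 0).all()

    def test_synthetic_points_on_segments(self):
        """Minority synthetics are convex combinations of two original
        minority points (k=1 pins the neighbor)."""
        X = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 10.0], [11.0, 10.0],
                      [10.0, 11.0], [11.0, 11.0]])
        y = np.array([1, 1, 0, 0, 0, 0])
        Xo, yo, prov = L.smote_oversample(X, y, k=1, seed=3)
        synth = Xo[prov == -1]
        assert len(synth) == 2 and (yo[prov == -1] == 1).all()
        for s in synth:
            # on the segment between the two minority points
            assert s[1] == pytest.approx(0.0)
            assert 0.0 <= s[0] <= 1.0
        # originals first, untouched
        np.testing.assert_array_equal(Xo[:6], X)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (30, 4))
        y = np.array([0] * 20 + [1] * 10)
        a = L.smote_oversample(X, y, k=3, seed=9)
        b = L.smote_oversample(X, y, k=3, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_singleton_class_rejected(self):
        X = np.zeros((3, 2))
        y = np.array([0, 0, 1])
        with pytest.raises(ConfigError, match="single sample"):
            L.smote_oversample(X, y, k=1, seed=0)


class TestCVEvaluate:
    def test_separable_data_scores_one(self):
        X, y = three_class_problem(0, n_samples=(20, 20, 20), n_features=6,
                                   n_inf=4, effect=8.0)
        score = L.cv_evaluate(X, y, list(X.columns), DEFAULT_SPEC, 5, seed=0)
        assert score == 1.0

    def test_permuted_labels_score_near_chance(self):
        """Mean score over label permutations sits near 1/3 for three equal
        classes."""
        X, y = three_class_problem(1, n_samples=(20, 20, 20), n_features=8,
                                   n_inf=0)
        rng = np.random.default_rng(2)
        scores = [L.cv_evaluate(X, rng.permutation(y), list(X.columns),
                                DEFAULT_SPEC, 5, seed=s)
                  for s in range(50)]
        assert 0.25 <= np.mean(scores) <= 0.42

    def test_no_synthetic_rows_in_test_folds(self):
        X, y = three_class_problem(3, n_samples=(25, 10, 30), n_features=10,
                                   n_inf=3)
        score, info = L.cv_evaluate(X, y, list(X.columns)[:5], DEFAULT_SPEC,
                                    5, seed=0, return_fold_info=True)
        seen_test = []
        for fold in info:
            # training provenance: originals first, synthetics flagged -1,
            # and the test fold indexes only real rows
            prov = fold["train_provenance"]
            assert (prov[prov >= 0] == np.arange((prov >= 0).sum())).all()
            assert (prov == -1).sum() > 0  # imbalanced -> SMOTE ran
            seen_test.extend(fold["test_indices"])
        assert sorted(seen_test) == list(range(len(y)))

    def test_unknown_feature_rejected(self):
        X, y = three_class_problem(4, n_features=5, n_inf=0)
        with pytest.raises(ConfigError, match="GHOST"):
            L.cv_evaluate(X, y, ["GHOST"], DEFAULT_SPEC, 5, seed=0)

    def test_cache_hits_recorded(self):
        X, y = three_class_problem(5, n_features=6, n_inf=2)
        ev = SubsetEvaluator(X, y, DEFAULT_SPEC, 5, 0)
        ev.score(["INF0", "INF1"])
        ev.score(["INF1", "INF0"])
        assert ev.cache_hits == 1 and ev.n_evaluations == 1


class TestGridSearch:
    def test_single_candidate_returned(self):
        X, y = three_class_problem(6, n_samples=(12, 12, 12), n_features=5,
                                   n_inf=2)
        spec = L.grid_search_model(
            X, y, [("svm", {"kernel": ["linear"], "C": [1]})], 3, 0)
        assert spec.model == "svm" and spec.param_dict["C"] == 1

    def test_tie_breaks_by_declaration_order(self):
        X, y = three_class_problem(7, n_samples=(12, 12, 12), n_features=5,
                                   n_inf=2)
        cands = [("svm", {"kernel": ["linear"], "C": [10]}),
                 ("svm", {"kernel": ["linear"], "C": [10]})]
        # identical specs score identically -> the first grid wins
        spec = L.grid_search_model(X, y, cands, 3, 0)
        assert spec == L.ClassifierSpec.make("svm", kernel="linear", C=10)

    def test_empty_grid_rejected(self):
        X, y = three_class_problem(8, n_features=4, n_inf=0)
        with pytest.raises(ConfigError):
            L.grid_search_model(X, y, [("svm", {})], 3, 0)

    def test_separable_data_reaches_one(self):
        X, y = three_class_problem(9, n_samples=(15, 15, 15), n_features=6,
                                   n_inf=4, effect=8.0)
        spec = L.grid_search_model(
            X, y, [("svm", {"kernel": ["linear"], "C": [1]})], 3, 0)
        assert L.cv_evaluate(X, y, list(X.columns), spec, 3, 0) == 1.0


class TestRFECV:
    def test_recovers_planted_informative_features(self):
        """Planted informative features survive elimination among noise in
        >= 90% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            X, y = three_class_problem(100 + seed, n_samples=(25, 20, 30),
                                       n_features=100, n_inf=5, effect=2.5)
            kept = L.rfecv_select(X, y, DEFAULT_SPEC, 5, seed)
            hits += int(all(f"INF{j}" in kept for j in range(5)))
        assert hits >= int(0.9 * n_seeds)

    def test_single_feature_returned_as_is(self):
        X, y = three_class_problem(10, n_features=1, n_inf=1)
        assert L.rfecv_select(X, y, DEFAULT_SPEC, 3, 0) == ["INF0"]

    def test_screen_prefilter_applied(self):
        X, y = three_class_problem(11, n_features=30, n_inf=3, effect=3.0)
        p = pd.Series(1.0, index=X.columns)
        p[["INF0", "INF1", "INF2"]] = 1e-6
        kept = L.rfecv_select(X, y, DEFAULT_SPEC, 3, 0, screen_p=p)
        assert set(kept) <= {"INF0", "INF1", "INF2"}


def _reward_table(seed, features):
    """Deterministic memoized reward with the structure cross-validated
    balanced accuracy has on this problem class: concave gains for planted
    informative features, a slight penalty plus deterministic jitter for
    uninformative additions.  Enumerated exhaustively for the oracle."""
    rng = np.random.default_rng(seed)
    informative = set(rng.choice(features, size=3, replace=False))
    jitter = {}
    table = {}
    gains = [0.25, 0.15, 0.08]
    for r in range(1, len(features) + 1):
        for combo in itertools.combinations(sorted(features), r):
            key = frozenset(combo)
            n_inf = len(key & informative)
            n_noise = r - n_inf
            j = float(rng.uniform(-0.002, 0.002))
            jitter[key] = j
            table[key] = 0.45 + sum(gains[:n_inf]) - 0.004 * n_noise + j
    return table


class TestMCTS:
    def test_exhaustive_oracle_equivalence(self):
        """On <= 8 candidates with a deterministic memoized reward, the search
        attains the exhaustive-enumeration optimum in every seeded run."""
        features = [f"f{i}" for i in range(8)]
        wins = 0
        for seed in range(20):
            table = _reward_table(seed, features)
            cfg = MCTSConfig(depth=3, trees_factor=10, seed=seed,
                             accept_threshold=0.99)
            res = mcts_feature_search(None, None, features, cfg=cfg,
                                      reward_fn=lambda s: table[frozenset(s)])
            best = max(table.values())
            wins += int(res.balanced_accuracy == pytest.approx(best))
        assert wins == 20

    def test_perfect_single_feature_selected_then_stop(self):
        features = ["good", "n1", "n2", "n3"]
        def reward(subset):
            return 1.0 if "good" in subset else 0.3
        cfg = MCTSConfig(depth=3, trees_factor=10, seed=0)
        res = mcts_feature_search(None, None, features, cfg=cfg,
                                  reward_fn=reward)
        assert res.features == ["good"]
        assert res.balanced_accuracy == 1.0
        stops = [a for _, a, _ in res.search_trace if a == STOP]
        assert stops  # the stop action fired

    def test_determinism_of_trace(self):
        X, y = three_class_problem(12, n_samples=(15, 10, 20), n_features=10,
                                   n_inf=3, effect=2.5)
        cfg = MCTSConfig(depth=3, seed=5)
        a = L.mcts_feature_search(X, y, list(X.columns)[:6], DEFAULT_SPEC, cfg)
        b = L.mcts_feature_search(X, y, list(X.columns)[:6], DEFAULT_SPEC, cfg)
        assert a.features == b.features
        assert a.search_trace == b.search_trace
        assert a.qualifying_subsets == b.qualifying_subsets

    def test_zero_budget_rejected(self):
        with pytest.raises(ConfigError):
            MCTSConfig(trees_factor=0).validate()

    def test_empty_candidates_rejected(self):
        with pytest.raises(ConfigError):
            mcts_feature_search(None, None, [], cfg=MCTSConfig(),
                                reward_fn=lambda s: 0.0)


class TestRefine:
    def test_frequent_feature_in_initial_set(self):
        qualifying = [(("f1", "f2"), 0.95), (("f1", "f3"), 0.94),
                      (("f1", "f4"), 0.93)]
        table = {frozenset(s): v for s, v in qualifying}
        def reward(subset):
            return table.get(frozenset(subset), 0.5)
        cfg = MCTSConfig(depth=2, refine_init_size=1, seed=0)
        res = refine_signature(qualifying, None, None, cfg=cfg,
                               candidate_features=["f1", "f2", "f3", "f4"],
                               reward_fn=reward)
        assert "f1" in res.features

    def test_empty_qualifying_falls_back(self):
        fallback = L.SignatureResult(features=["x"], balanced_accuracy=0.7)
        res = refine_signature([], None, None, cfg=MCTSConfig(),
                               reward_fn=lambda s: 0.0, fallback=fallback)
        assert res is fallback

    def test_refined_score_at_least_initial(self):
        for seed in range(5):
            X, y = three_class_problem(40 + seed, n_samples=(15, 10, 20),
                                       n_features=12, n_inf=3, effect=2.0)
            ev = SubsetEvaluator(X, y, DEFAULT_SPEC, 5, seed)
            reward = lambda s: ev.score(sorted(s))  # noqa: E731
            cfg = MCTSConfig(depth=3, seed=seed, accept_threshold=0.5)
            first = mcts_feature_search(X, y, list(X.columns)[:8],
                                        DEFAULT_SPEC, cfg, reward_fn=reward)
            if not first.qualifying_subsets:
                continue
            cfg2 = MCTSConfig(depth=3, seed=seed, accept_threshold=0.5,
                              refine_init_size=3)
            res = refine_signature(first.qualifying_subsets, X, y,
                                   DEFAULT_SPEC, cfg2,
                                   candidate_features=list(X.columns)[:8],
                                   reward_fn=reward, fallback=first)
            init = [f for f, _ in sorted(
                ((f, sum(f in s for s, _ in first.qualifying_subsets))
                 for s, _ in first.qualifying_subsets for f in s),
                key=lambda t: -t[1])][:3]
            assert res.balanced_accuracy >= reward(frozenset(init)) - 1e-12


class TestEvaluateSignature:
    def test_separable_classes_get_unit_auc(self):
        X, y = three_class_problem(13, n_samples=(20, 15, 25), n_features=8,
                                   n_inf=4, effect=8.0)
        res = L.evaluate_signature(X, y, [f"INF{j}" for j in range(4)],
                                   DEFAULT_SPEC, 5, seed=0)
        assert all(v == 1.0 for v in res.per_class_auc.values())
        assert res.balanced_accuracy == 1.0
        assert res.pca_coordinates.shape[0] == len(y)

    def test_auc_antisymmetry_under_score_negation(self):
        from lrrksig.signature import _roc_auc
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 100)
        scores = rng.normal(size=100)
        assert _roc_auc(truth, scores) == pytest.approx(
            1.0 - _roc_auc(truth, -scores))

    def test_random_scores_near_half_auc(self):
        from lrrksig.signature import _roc_auc
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(50):
            truth = np.repeat([0, 1], 50)
            aucs.append(_roc_auc(truth, rng.normal(size=100)))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_matches_sklearn_roc_auc(self):
        from sklearn.metrics import roc_auc_score
        from lrrksig.signature import _roc_auc
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, 300)
        scores = np.round(rng.normal(size=300), 1)  # ties included
        assert _roc_auc(truth, scores) == pytest.approx(
            roc_auc_score(truth, scores))
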