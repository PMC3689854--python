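"""Best-First tree, cross-validation pruning, Multi-boosting, evaluation."""

import json
import math

import numpy as np
import pytest

from mireader.classify import (
    MultiBoostModel, evaluate_predictions, load_models, prune_bftree,
    rank_auc, save_models, subcommittee_terminations, train_bftree,
    train_multiboost, _best_split, _Node, BFTree,
)
from oracles import best_split_oracle


class TestBFTree:
    def test_separable_1d_single_split(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        tree = train_bftree(X, y)
        assert tree.n_expansions == 1
        assert tree.root.threshold == pytest.approx(5.5)
        assert (tree.predict(X) == y).all()

    def test_single_class_single_leaf(self):
        tree = train_bftree(np.array([[1.0], [2.0]]), np.array([1, 1]))
        assert tree.n_expansions == 0
        assert tree.predict_one(np.array([5.0])) == 1

    def test_xor_resolved_at_depth_two(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        y = np.array([0, 1, 1, 0])
        tree = train_bftree(X, y, min_leaf=1)
        assert (tree.predict(X) == y).all()
        assert tree.n_expansions <= 3

    def test_constant_features_single_leaf(self):
        X = np.ones((6, 2))
        y = np.array([0, 1, 0, 1, 0, 0])
        tree = train_bftree(X, y)
        assert tree.n_expansions == 0
        assert tree.root.majority == 0

    def test_split_matches_exhaustive_enumeration(self, rng):
        """First split agrees with brute-force search over every candidate
        (feature, midpoint) on small random datasets."""
        for _ in range(300):
            n = int(rng.integers(2, 7))
            d = int(rng.integers(1, 4))
            X = rng.integers(0, 5, size=(n, d)).astype(float)
            y = rng.integers(0, 2, size=n)
            w = rng.uniform(0.2, 2.0, size=n)
            got = _best_split(X, y, w)
            want = best_split_oracle(X, y, w)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got[0] == pytest.approx(want[0])
                assert got[1] == want[1]
                assert got[2] == pytest.approx(want[2])

    def test_weighted_split_shifts_with_weights(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 1, 0, 1])
        # heavy weight makes isolating instance 1 the best gain
        w = np.array([1.0, 50.0, 1.0, 1.0])
        tree = train_bftree(X, y, sample_weight=w, min_leaf=1)
        assert tree.predict_one(np.array([1.0])) == 1


class TestPruning:
    def test_noise_free_tree_retained(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0], [12.0], [-1.0]])
        y = np.array([0, 0, 1, 1, 1, 0])
        tree = train_bftree(X, y)
        pruned = prune_bftree(tree, X, y, folds=3, seed=0)
        assert pruned.effective_size >= 1
        assert (pruned.predict(X) == y).all()

    def test_pure_noise_collapses_to_root(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, size=60)
        tree = train_bftree(X, y, min_leaf=1)
        assert tree.n_expansions > 0
        pruned = prune_bftree(tree, X, y, folds=5, seed=0)
        assert pruned.effective_size <= max(1, tree.n_expansions // 4)

    def test_never_grows(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        tree = train_bftree(X, y)
        pruned = prune_bftree(tree, X, y, folds=2, seed=3)
        assert pruned.effective_size <= tree.n_expansions

    def test_too_few_instances_skips(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        tree = train_bftree(X, y, min_leaf=1)
        pruned = prune_bftree(tree, X, y, folds=5)
        assert pruned.prune_level is None


class TestMultiBoost:
    def _data(self, rng, n=120, flip=0.0):
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        if flip:
            mask = rng.random(n) < flip
            y[mask] = 1 - y[mask]
        return X, y

    def test_weight_conservation_identity(self, rng):
        X, y = self._data(rng, flip=0.25)
        model = train_multiboost(X, y, K=30, seed=5, max_expansions=3)
        assert model.weight_residuals, "no reweighting steps exercised"
        assert max(model.weight_residuals) < 1e-9

    def test_separable_first_tree_capped_vote(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]] * 10)
        y = np.array([0, 0, 1, 1] * 10)
        model = train_multiboost(X, y, K=30, seed=0)
        assert model.vote_weights[0] == pytest.approx(math.log(1e10))
        assert (model.predict(X) == y).all()

    def test_subcommittee_terminations(self):
        assert subcommittee_terminations(30) == [5, 10, 15, 20, 25, 30]
        assert subcommittee_terminations(100) == [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        assert subcommittee_terminations(1) == [1]

    def test_single_class_degenerates_to_leaf(self):
        model = train_multiboost(np.ones((5, 2)), np.ones(5, dtype=int), K=30)
        assert len(model.trees) == 1
        assert model.predict_one(np.zeros(2))[0] == 1

    def test_vote_tally_and_tiebreak(self):
        def leaf(cls):
            return BFTree(_Node(float(cls), float(1 - cls)), 0)

        model = MultiBoostModel(
            trees=[leaf(1), leaf(0), leaf(0)],
            vote_weights=[2.0, 1.0, 1.0],
            subcommittee_bounds=[1, 2, 3], K=3, seed=0, n_features=1,
            class_prior_pos=0.5,
        )
        # pos weight 2 vs neg weight 2: tie -> negative (prior not > 0.5)
        cls, score = model.predict_one(np.zeros(1))
        assert cls == 0 and score == pytest.approx(0.5)
        model.class_prior_pos = 0.6
        assert model.predict_one(np.zeros(1))[0] == 1

    def test_unanimous_score_one(self):
        def leaf():
            return BFTree(_Node(3.0, 1.0), 0)

        model = MultiBoostModel([leaf()] * 3, [0.5, 1.5, 2.0], [1, 2, 3],
                                3, 0, 1)
        cls, score = model.predict_one(np.zeros(1))
        assert cls == 1 and score == 1.0

    def test_fixed_seed_byte_identical_serialization(self, rng, tmp_path):
        X, y = self._data(rng, flip=0.15)
        a = train_multiboost(X, y, K=30, seed=9, max_expansions=4)
        b = train_multiboost(X, y, K=30, seed=9, max_expansions=4)
        pa, pb = tmp_path / "a.json", tmp_path / "b.json"
        save_models({21: a}, pa)
        save_models({21: b}, pb)
        assert pa.read_bytes() == pb.read_bytes()
        loaded = load_models(pa)[21]
        assert loaded.vote_weights == a.vote_weights
        assert (loaded.predict(X) == a.predict(X)).all()

    def test_noisy_data_still_learns(self, rng):
        X, y = self._data(rng, n=300, flip=0.1)
        Xt, yt = self._data(np.random.default_rng(77), n=300)
        model = train_multiboost(X, y, K=30, seed=2, max_expansions=6)
        assert (model.predict(Xt) == yt).mean() > 0.8


class TestEvaluation:
    def test_perfect_toy_set_maxima(self):
        labels = np.array([1, 1, 0, 0])
        preds = labels.copy()
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        rep = evaluate_predictions(labels, preds, scores)
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0
        assert rep.mcc == 1.0 and rep.auc == 1.0

    def test_inverted_predictions(self):
        labels = np.array([1, 1, 0, 0])
        rep = evaluate_predictions(labels, 1 - labels,
                                   np.array([0.1, 0.2, 0.8, 0.9]))
        assert rep.accuracy == 0.0 and rep.mcc == -1.0 and rep.auc == 0.0

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(25):
            labels = rng.integers(0, 2, size=50)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(50), 2)  # force ties
            assert rank_auc(labels, scores) == pytest.approx(
                roc_auc_score(labels, scores)
            )

    def test_auc_needs_both_classes(self):
        with pytest.raises(ValueError):
            rank_auc(np.ones(4), np.random.rand(4))


def test_evaluation_exports(tmp_path):
    import numpy as np

    from mireader.classify import write_evaluation_tsv, write_roc_points

    labels = np.array([1, 1, 0, 0])
    scores = np.array([0.9, 0.6, 0.6, 0.1])
    rep = evaluate_predictions(labels, (scores >= 0.5).astype(int), scores)
    write_evaluation_tsv(rep, tmp_path / "report.tsv")
    write_roc_points(labels, scores, tmp_path / "roc.csv")
    assert "accuracy_pct" in (tmp_path / "report.tsv").read_text()
    roc = (tmp_path / "roc.csv").read_text().splitlines()
    assert roc[0] == "threshold,fpr,tpr"
    assert roc[-1].endswith(",1,1")  # lowest threshold calls everything
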