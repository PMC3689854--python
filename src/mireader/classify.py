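"""Best-First decision trees and the Multi-boosting ensemble.

The base learner is a binary decision tree grown best-first: instead of
depth-first recursion, a frontier of expandable leaves is kept and the leaf
whose best binary split yields the greatest weighted Gini impurity reduction
is expanded next.  Because expansions are globally ordered, post-pruning
reduces to choosing how many expansions to keep, which is done by 5-fold
cross-validation (ties toward the shorter tree).

Multi-boosting wraps AdaBoost-style reweighting inside subcommittees and
resets instance weights between subcommittees with wagging draws from a
continuous Poisson approximation (w = -ln U, U ~ Uniform(0,1]).  Vote weight
of classifier t is log((1-e)/e) for weighted error e; error-free classifiers
get the capped weight log(1/beta) with beta = 1e-10.  After reweighting
(misclassified x 1/(2e), correct x 1/(2(1-e))) the total weight is exactly
conserved at n, which the trainer verifies continuously.

Class convention: label 1 = miRNA (positive), 0 = non-miRNA.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

#: vote-weight cap for error-free base classifiers
BETA_FLOOR = 1e-10
#: instance-weight floor applied before renormalisation
WEIGHT_FLOOR = 1e-8
#: bounded retries for the e > 0.5 wagging-reset loop
MAX_RESAMPLE_RETRIES = 3


# ---------------------------------------------------------------------------
# Best-First tree


@dataclass
class _Node:
    """Tree node; internal iff ``feature`` is not None."""

    n_pos: float
    n_neg: float
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None
    expansion_index: Optional[int] = None  # order in which this node was split

    @property
    def majority(self) -> int:
        # tie -> negative class
        return 1 if self.n_pos > self.n_neg else 0

    def to_dict(self) -> dict:
        d = {"n_pos": repr(self.n_pos), "n_neg": repr(self.n_neg)}
        if self.feature is not None:
            d.update(
                feature=self.feature,
                threshold=repr(self.threshold),
                expansion_index=self.expansion_index,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        node = cls(float(d["n_pos"]), float(d["n_neg"]))
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = float(d["threshold"])
            node.expansion_index = d["expansion_index"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _gini_total(w_pos: float, w_neg: float) -> float:
    """Weighted Gini impurity times the node weight: W * (1 - p^2 - q^2)."""
    w = w_pos + w_neg
    if w <= 0:
        return 0.0
    return w * (1.0 - (w_pos / w) ** 2 - (w_neg / w) ** 2)


#: gains closer than this are treated as tied (float-noise tolerance)
GAIN_TOL = 1e-12


def _best_split(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Exhaustive best binary split over all features and midpoints.

    Returns (gain, feature, threshold) or None when no value-separating
    threshold exists.  Candidate thresholds are midpoints between
    consecutive distinct sorted values; gain is the reduction in total
    weighted Gini.  Gains within ``GAIN_TOL`` are tied and break toward the
    lower feature index, then the lower threshold, so the search is
    deterministic.  A zero-gain split is still returned: on parity-like
    data (XOR) every first split is gain-free yet the children separate.
    """
    parent = _gini_total(float(w[y == 1].sum()), float(w[y == 0].sum()))
    best = None  # (gain, feature, threshold)
    for f in range(X.shape[1]):
        v = X[:, f]
        order = np.argsort(v, kind="stable")
        vs, ys, ws = v[order], y[order], w[order]
        wp = np.cumsum(ws * ys)          # prefix positive weight
        wt = np.cumsum(ws)               # prefix total weight
        total_pos, total = wp[-1], wt[-1]
        # split boundaries where the value actually changes
        change = np.nonzero(np.diff(vs) > 0)[0]
        for k in change:
            lp, lt = wp[k], wt[k]
            left = _gini_total(lp, lt - lp)
            right = _gini_total(total_pos - lp, (total - lt) - (total_pos - lp))
            gain = float(max(parent - left - right, 0.0))
            thr = float((vs[k] + vs[k + 1]) / 2.0)
            if (
                best is None
                or gain > best[0] + GAIN_TOL
                or (abs(gain - best[0]) <= GAIN_TOL and (f, thr) < best[1:])
            ):
                best = (gain, f, thr)
    return best


@dataclass
class BFTree:
    """Best-first-grown binary decision tree with an expansion ordering.

    ``n_expansions`` is the number of splits actually performed;
    ``prune_level`` (None = full) truncates prediction to the first k
    expansions, which is how cross-validation post-pruning is realised.
    """

    root: _Node
    n_expansions: int
    prune_level: Optional[int] = None

    def predict_one(self, x: np.ndarray) -> int:
        limit = self.prune_level
        node = self.root
        while node.feature is not None:
            if limit is not None and node.expansion_index >= limit:
                break
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.majority

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.predict_one(x) for x in np.asarray(X)])

    @property
    def effective_size(self) -> int:
        return self.n_expansions if self.prune_level is None else self.prune_level


def train_bftree(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: Optional[np.ndarray] = None,
    min_leaf: int = 2,
    max_expansions: Optional[int] = None,
) -> BFTree:
    """Grow a Best-First tree on (optionally weighted) binary-labelled data.

    A frontier of expandable leaves is ranked by the weighted Gini gain of
    each leaf's best split; the top leaf is expanded until every leaf is
    pure, too small (<= ``min_leaf`` instances), gain-free, or the expansion
    budget is exhausted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if len(X) == 0:
        raise ValueError("no instances")
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)

    def make_node(idx: np.ndarray) -> _Node:
        wp = float(w[idx][y[idx] == 1].sum())
        wn = float(w[idx][y[idx] == 0].sum())
        return _Node(wp, wn)

    all_idx = np.arange(len(y))
    root = make_node(all_idx)
    # frontier entries: (-gain, creation order, leaf, split, idx)
    frontier: list = []
    creation = 0

    def consider(node: _Node, idx: np.ndarray) -> None:
        nonlocal creation
        if len(idx) <= min_leaf:
            return
        if node.n_pos == 0 or node.n_neg == 0:  # purity 1 -> unexpanded
            return
        split = _best_split(X[idx], y[idx], w[idx])
        if split is None:
            return
        frontier.append(((-split[0], creation), node, split, idx))
        creation += 1

    consider(root, all_idx)
    n_exp = 0
    while frontier and (max_expansions is None or n_exp < max_expansions):
        frontier.sort(key=lambda e: e[0])
        _, node, (gain, f, thr), idx = frontier.pop(0)
        mask = X[idx, f] <= thr
        li, ri = idx[mask], idx[~mask]
        node.feature, node.threshold, node.expansion_index = f, thr, n_exp
        node.left, node.right = make_node(li), make_node(ri)
        n_exp += 1
        consider(node.left, li)
        consider(node.right, ri)
    return BFTree(root, n_exp)


def prune_bftree(
    tree: BFTree,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    min_leaf: int = 2,
) -> BFTree:
    """Cross-validation post-pruning: pick the expansion count minimising
    mean CV misclassification (ties -> the shorter tree) and truncate.

    Too few instances to fold -> the tree is returned unpruned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n = len(y)
    if n < folds:
        import logging
        logging.getLogger(__name__).warning(
            "only %d instances for %d folds; skipping pruning", n, folds
        )
        return tree
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(np.arange(n) % folds)
    max_k = tree.n_expansions
    errors = np.zeros(max_k + 1)
    for f in range(folds):
        val = assignment == f
        if val.all() or (~val).all():
            continue
        sub = train_bftree(X[~val], y[~val], min_leaf=min_leaf)
        for k in range(max_k + 1):
            sub.prune_level = min(k, sub.n_expansions)
            errors[k] += float((sub.predict(X[val]) != y[val]).sum())
    best_k = int(np.argmin(errors))  # argmin takes the first (shortest) tie
    pruned = BFTree(tree.root, tree.n_expansions, prune_level=best_k)
    return pruned


# ---------------------------------------------------------------------------
# Multi-boosting


@dataclass
class MultiBoostModel:
    """Weighted committee of Best-First trees for one length cluster."""

    trees: list[BFTree]
    vote_weights: list[float]
    subcommittee_bounds: list[int]
    K: int
    seed: int
    n_features: int
    class_prior_pos: float = 0.5
    weight_residuals: list[float] = field(default_factory=list)

    def predict_one(self, x: np.ndarray) -> tuple[int, float]:
        votes = {0: 0.0, 1: 0.0}
        for tree, vw in zip(self.trees, self.vote_weights):
            votes[tree.predict_one(x)] += vw
        total = votes[0] + votes[1]
        if total <= 0:
            return 0, 0.5
        if votes[1] > votes[0]:
            cls = 1
        elif votes[0] > votes[1]:
            cls = 0
        else:  # tie -> class with the higher training prior, then negative
            cls = 1 if self.class_prior_pos > 0.5 else 0
        return cls, votes[cls] / total

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.predict_one(x)[0] for x in np.asarray(X, float)])

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class vote share in [0, 1] (0.5 at a tie) for ranking."""
        out = []
        for x in np.asarray(X, float):
            votes = {0: 0.0, 1: 0.0}
            for tree, vw in zip(self.trees, self.vote_weights):
                votes[tree.predict_one(x)] += vw
            total = votes[0] + votes[1]
            out.append(votes[1] / total if total > 0 else 0.5)
        return np.array(out)

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "seed": self.seed,
            "n_features": self.n_features,
            "class_prior_pos": repr(self.class_prior_pos),
            "subcommittee_bounds": self.subcommittee_bounds,
            "vote_weights": [repr(v) for v in self.vote_weights],
            "trees": [
                {"n_expansions": t.n_expansions, "prune_level": t.prune_level,
                 "root": t.root.to_dict()}
                for t in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultiBoostModel":
        trees = [
            BFTree(_Node.from_dict(t["root"]), t["n_expansions"], t["prune_level"])
            for t in d["trees"]
        ]
        return cls(
            trees=trees,
            vote_weights=[float(v) for v in d["vote_weights"]],
            subcommittee_bounds=list(d["subcommittee_bounds"]),
            K=d["K"],
            seed=d["seed"],
            n_features=d["n_features"],
            class_prior_pos=float(d["class_prior_pos"]),
        )


def subcommittee_terminations(K: int) -> list[int]:
    """Termination iterations for ceil(sqrt(K)) equal-sized subcommittees."""
    s = math.ceil(math.sqrt(K))
    return [math.ceil(i * K / s) for i in range(1, s + 1)]


def train_multiboost(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 100,
    seed: int = 0,
    min_leaf: int = 2,
    max_expansions: Optional[int] = 15,
) -> MultiBoostModel:
    """Boosting-with-wagging over Best-First trees.

    Instance weights start uniform (summing to n).  At each subcommittee
    boundary they are reset to wagging draws w = -ln(U) and rescaled to sum
    n; within a subcommittee AdaBoost-style reweighting applies.  A base
    classifier with weighted error e > 0.5 triggers a wagging reset and
    refit (at most ``MAX_RESAMPLE_RETRIES`` times, then training stops);
    e = 0 earns the capped vote weight and also closes the subcommittee.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if K < 1:
        raise ValueError("K must be >= 1")
    classes = set(np.unique(y))
    n = len(y)
    prior_pos = float((y == 1).mean())
    if classes != {0, 1}:
        # degenerate training set: a single majority-class leaf
        leaf = _Node(float((y == 1).sum()), float((y == 0).sum()))
        return MultiBoostModel([BFTree(leaf, 0)], [1.0], [1], K, seed, X.shape[1],
                               prior_pos)
    rng = np.random.default_rng(seed)
    terminations = subcommittee_terminations(K)
    residuals: list[float] = []

    def wagging_reset() -> np.ndarray:
        u = 1.0 - rng.random(n)  # U in (0, 1]
        w = -np.log(u)
        w = np.maximum(w, WEIGHT_FLOOR)
        return w * (n / w.sum())

    w = np.ones(n, dtype=float)
    sub_i = 0
    trees: list[BFTree] = []
    vote_weights: list[float] = []
    bounds: list[int] = []
    stopped = False
    for t in range(1, K + 1):
        if sub_i < len(terminations) and terminations[sub_i] == t:
            w = wagging_reset()
            sub_i += 1
        retries = 0
        while True:
            tree = train_bftree(X, y, sample_weight=w, min_leaf=min_leaf,
                                max_expansions=max_expansions)
            mis = tree.predict(X) != y
            e = float(w[mis].sum()) / n
            if e <= 0.5:
                break
            retries += 1
            if retries > MAX_RESAMPLE_RETRIES:
                stopped = True
                break
            w = wagging_reset()
            sub_i += 1
        if stopped:
            break
        if e == 0.0:
            trees.append(tree)
            vote_weights.append(math.log(1.0 / BETA_FLOOR))
            bounds.append(t)
            w = wagging_reset()
            sub_i += 1
        else:
            trees.append(tree)
            vote_weights.append(math.log((1.0 - e) / e))
            bounds.append(t)
            w = w.copy()
            w[mis] *= 1.0 / (2.0 * e)
            w[~mis] *= 1.0 / (2.0 * (1.0 - e))
            # the x1/(2e), x1/(2(1-e)) rules conserve the total weight at n
            # exactly; record the residual before flooring as evidence
            residuals.append(abs(float(w.sum()) - n))
            w = np.maximum(w, WEIGHT_FLOOR)
            w *= n / w.sum()
    if not trees:
        leaf = _Node(float((y == 1).sum()), float((y == 0).sum()))
        trees, vote_weights, bounds = [BFTree(leaf, 0)], [1.0], [1]
    model = MultiBoostModel(trees, vote_weights, bounds, K, seed, X.shape[1],
                            prior_pos, residuals)
    return model


# ---------------------------------------------------------------------------
# model sets, duplex classification, evaluation


def save_models(models: dict[int, MultiBoostModel], path: str | Path) -> None:
    payload = {
        "format_version": 1,
        "clusters": {str(L): m.to_dict() for L, m in sorted(models.items())},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def load_models(path: str | Path) -> dict[int, MultiBoostModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return {int(L): MultiBoostModel.from_dict(d)
            for L, d in payload["clusters"].items()}


def _fit_width(values: np.ndarray, width: int) -> np.ndarray:
    if len(values) == width:
        return values
    if len(values) > width:
        return values[:width]
    return np.concatenate([values, np.zeros(width - len(values))])


def route_to_model(
    cluster: int, models: dict[int, MultiBoostModel]
) -> tuple[int, MultiBoostModel]:
    """The model for a cluster, falling back to the nearest-length model."""
    if not models:
        raise ValueError("no models available")
    if cluster in models:
        return cluster, models[cluster]
    L = min(models, key=lambda k: (abs(k - cluster), k))
    return L, models[L]


@dataclass
class DuplexCall:
    top_id: str
    bottom_id: str
    predicted_class: int
    score: float
    cluster: int
    rscore: float
    is_mirna: bool
    top_count: int = 0
    bottom_count: int = 0


def classify_duplexes(
    duplexes,
    profiles: dict,
    models: dict[int, MultiBoostModel],
    threshold: float = 0.9,
) -> list[DuplexCall]:
    """Featurize each duplex, route it to its representative cluster's model
    and call it a miRNA iff the predicted class is miRNA with vote share at
    or above ``threshold`` (0.9 for novel discovery, 0.5 for evaluation)."""
    from .profiles import featurize

    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0.5, 1]")
    calls: list[DuplexCall] = []
    for d in duplexes:
        fv = featurize(d.pattern, profiles)
        cluster, model = route_to_model(fv.representative_profile, models)
        x = _fit_width(fv.values, model.n_features)
        cls, score = model.predict_one(x)
        calls.append(
            DuplexCall(
                d.top_id, d.bottom_id, cls, score, cluster, fv.rscore,
                is_mirna=(cls == 1 and score >= threshold),
                top_count=d.top_count, bottom_count=d.bottom_count,
            )
        )
    return calls


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney statistic with midrank tie handling)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(scores), dtype=float)
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # midrank, 1-based
        i = j + 1
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "sensitivity_pct": round(self.sensitivity * 100, 4),
            "specificity_pct": round(self.specificity * 100, 4),
            "accuracy_pct": round(self.accuracy * 100, 4),
            "mcc": round(self.mcc, 6),
            "auc": round(self.auc, 6),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def write_evaluation_tsv(report: "EvaluationReport", path: str | Path) -> None:
    d = report.to_dict()
    with open(path, "w") as fh:
        fh.write("\t".join(d) + "\n")
        fh.write("\t".join(str(v) for v in d.values()) + "\n")


def write_roc_points(
    labels: np.ndarray, scores: np.ndarray, path: str | Path
) -> None:
    """CSV of (threshold, FPR, TPR) points for an ROC plot."""
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    n_pos = max(int((labels == 1).sum()), 1)
    n_neg = max(int((labels == 0).sum()), 1)
    with open(path, "w") as fh:
        fh.write("threshold,fpr,tpr\n")
        for thr in sorted(set(scores), reverse=True):
            called = scores >= thr
            tpr = ((labels == 1) & called).sum() / n_pos
            fpr = ((labels == 0) & called).sum() / n_neg
            fh.write(f"{thr:.6g},{fpr:.6g},{tpr:.6g}\n")


def evaluate_predictions(
    labels: np.ndarray,
    predictions: np.ndarray,
    scores: Optional[np.ndarray] = None,
) -> EvaluationReport:
    """Sensitivity, specificity, accuracy, MCC and rank-based AUC."""
    labels = np.asarray(labels, int)
    predictions = np.asarray(predictions, int)
    tp = int(((labels == 1) & (predictions == 1)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    sens = tp / n_pos if n_pos else 0.0
    spec = tn / n_neg if n_neg else 0.0
    acc = (tp + tn) / len(labels)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    auc = rank_auc(labels, scores) if scores is not None else float("nan")
    return EvaluationReport(sens, spec, acc, mcc, auc, n_pos, n_neg)
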