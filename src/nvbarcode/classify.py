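"""Bagged-tree taxonomic classification with OOB evaluation and ROC curves.

The classifier is a bagging ensemble of decision trees: each tree is grown on
a bootstrap resample and casts a unit vote; prediction is the plurality vote.
Accuracy is evaluated out-of-bag (OOB) — each sample is scored only by the
trees whose bootstrap omitted it — which gives an unbiased error estimate
without a held-out split.

The ROC construction differs from the usual threshold sweep: for each tree
count k in a grid, one point is produced by macro-averaging the one-vs-rest
true- and false-positive rates over all classes, using OOB-vote predictions;
the curve is these points sorted by FPR with (0,0) and (1,1) anchors, and the
AUC is the trapezoidal area under it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted


class BarcodeForest(BaseEstimator, ClassifierMixin):
    """Bagging ensemble of unit-vote decision trees with OOB bookkeeping.

    Parameters
    ----------
    n_estimators : int, default 20
        Number of trees. Tree i of an ``n``-tree forest equals tree i of any
        larger forest grown from the same ``random_state`` (nested prefix
        property), so OOB error as a function of tree count can be read off
        one fitted model.
    max_features : "sqrt" | int | float | None, default "sqrt"
        Features considered per split (random-forest style subsampling).
    random_state : int, default 0
        Seeds bootstraps and tree randomness; fixed seed gives
        bit-reproducible predictions.
    """

    def __init__(self, n_estimators: int = 20, max_features="sqrt",
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        self.bootstrap_indices_ = []
        for _ in range(self.n_estimators):
            idx = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y_enc[idx])
            self.estimators_.append(tree)
            self.bootstrap_indices_.append(idx)
        self._oob_votes = self._vote_matrix(X, oob_only=True)
        self.oob_decision_votes_ = self._oob_votes
        self.oob_error_ = self._oob_error(self._oob_votes, y_enc)
        self.n_features_in_ = X.shape[1]
        self._y_enc = y_enc
        self._X_train_ = X
        return self

    def _vote_matrix(self, X, n_trees: int | None = None, oob_only: bool = False):
        """(n_samples, n_classes) unit-vote counts from the first ``n_trees`` trees."""
        n_trees = len(self.estimators_) if n_trees is None else n_trees
        votes = np.zeros((X.shape[0], self.classes_.size), dtype=np.int64)
        for t in range(n_trees):
            pred = self.estimators_[t].predict(X)
            if oob_only:
                inbag = np.zeros(X.shape[0], dtype=bool)
                inbag[self.bootstrap_indices_[t]] = True
                rows = np.flatnonzero(~inbag)
            else:
                rows = np.arange(X.shape[0])
            np.add.at(votes, (rows, pred[rows].astype(int)), 1)
        return votes

    @staticmethod
    def _plurality(votes: np.ndarray) -> np.ndarray:
        """Predicted class index per row; rows with zero votes get -1."""
        pred = votes.argmax(axis=1)
        pred[votes.sum(axis=1) == 0] = -1
        return pred

    @staticmethod
    def _oob_error(votes: np.ndarray, y_enc: np.ndarray) -> float:
        """Misclassification rate among samples with at least one OOB vote."""
        pred = BarcodeForest._plurality(votes.copy())
        covered = pred >= 0
        if not covered.any():
            return float("nan")
        return float((pred[covered] != y_enc[covered]).mean())

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        votes = self._vote_matrix(X)
        return self.classes_[votes.argmax(axis=1)]

    def oob_predictions(self, n_trees: int | None = None) -> np.ndarray:
        """OOB plurality-vote class index per training sample (-1 = no vote).

        Uses the first ``n_trees`` trees (all by default).
        """
        check_is_fitted(self, "estimators_")
        if n_trees is None or n_trees == len(self.estimators_):
            votes = self._oob_votes
        else:
            votes = self._vote_matrix(self._X_train_, n_trees, oob_only=True)
        return self._plurality(votes.copy())

def train_forest(X, y, n_trees: int = 20, seed: int = 0) -> BarcodeForest:
    """Fit a unit-vote bagged-tree ensemble; OOB error in ``model.oob_error_``."""
    return BarcodeForest(n_estimators=n_trees, random_state=seed).fit(X, y)


@dataclass(frozen=True)
class OOBCurve:
    tree_counts: tuple[int, ...]
    oob_error: tuple[float, ...]


def oob_curve(X, y, tree_counts, seed: int = 0) -> OOBCurve:
    """OOB error as a function of tree count, on nested prefix ensembles."""
    tree_counts = [int(t) for t in tree_counts]
    if any(b <= a for a, b in zip(tree_counts, tree_counts[1:])):
        raise ValueError("tree_counts must be strictly increasing")
    model = train_forest(X, y, n_trees=max(tree_counts), seed=seed)
    y_enc = model._y_enc
    errors = []
    for t in tree_counts:
        votes = model._vote_matrix(model._X_train_, t, oob_only=True)
        errors.append(model._oob_error(votes, y_enc))
    return OOBCurve(tuple(tree_counts), tuple(errors))


def evaluate_ranks(records, features, ranks=("class", "order", "family", "genus", "species"),
                   n_trees: int = 20, seed: int = 0) -> pd.DataFrame:
    """Per-rank OOB accuracy table (accuracy = 1 - OOB error).

    One model per taxonomic rank; ranks with a single label are skipped with
    a warning row (accuracy NaN).
    """
    import warnings

    X = np.asarray(features, dtype=float)
    rows = []
    for rank in ranks:
        labels = np.array([r.taxonomy.rank(rank) if r.taxonomy else "" for r in records])
        if np.unique(labels).size < 2:
            warnings.warn(f"rank {rank!r} has fewer than two labels; skipped")
            rows.append({"rank": rank, "n_labels": int(np.unique(labels).size),
                         "oob_error": float("nan"), "accuracy": float("nan")})
            continue
        model = train_forest(X, labels, n_trees=n_trees, seed=seed)
        rows.append({"rank": rank, "n_labels": int(model.classes_.size),
                     "oob_error": model.oob_error_,
                     "accuracy": 1.0 - model.oob_error_})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ROCResult:
    tree_counts: tuple[int, ...]
    tpr: tuple[float, ...]     # macro-averaged over the one-vs-rest splits
    fpr: tuple[float, ...]
    auc: float
    curve: np.ndarray = field(repr=False, default=None)  # FPR-sorted with anchors


def _macro_rates(pred: np.ndarray, y_enc: np.ndarray, n_classes: int):
    """Macro-averaged one-vs-rest TPR and FPR from predicted class indices.

    Samples without an OOB vote (pred == -1) are excluded. Classes with no
    positive (or no negative) covered samples are skipped in the average.
    """
    covered = pred >= 0
    p, t = pred[covered], y_enc[covered]
    tprs, fprs = [], []
    for c in range(n_classes):
        pos = t == c
        neg = ~pos
        if pos.sum() == 0 or neg.sum() == 0:
            continue
        tp = int(((p == c) & pos).sum())
        fn = int(((p != c) & pos).sum())
        fp = int(((p == c) & neg).sum())
        tn = int(((p != c) & neg).sum())
        tprs.append(tp / (tp + fn))
        fprs.append(fp / (fp + tn))
    return float(np.mean(tprs)), float(np.mean(fprs))


def roc_tree_sweep(X, y, tree_grid=(1, 2, 3, 5, 10, 15, 20, 30, 50), seed: int = 0) -> ROCResult:
    """ROC from macro-averaged OOB one-vs-rest rates across a tree-count grid.

    For each k in ``tree_grid`` the first-k-trees ensemble yields one
    (FPR, TPR) point; the curve is the FPR-sorted points with (0,0) and (1,1)
    anchors and the AUC its trapezoidal area.
    """
    tree_grid = [int(k) for k in tree_grid]
    if not tree_grid:
        raise ValueError("tree_grid must be nonempty")
    model = train_forest(X, y, n_trees=max(tree_grid), seed=seed)
    y_enc = model._y_enc
    tprs, fprs = [], []
    for k in sorted(tree_grid):
        pred = model.oob_predictions(k)
        tpr, fpr = _macro_rates(pred, y_enc, model.classes_.size)
        tprs.append(tpr)
        fprs.append(fpr)
    pts = np.array(sorted(zip(fprs, tprs)) + [(0.0, 0.0), (1.0, 1.0)])
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCResult(tuple(sorted(tree_grid)), tuple(tprs), tuple(fprs), auc, pts)
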