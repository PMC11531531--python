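"""Recursive feature elimination driven by entropy-criterion decision trees.

Each elimination round fits one decision tree per stratified fold, records the
mean fold accuracy, averages the trees' impurity-decrease importances, and
drops the least-important ``step`` fraction of the surviving features; rounds
repeat until ``target_n_features`` remain.  Chunked elimination keeps the
procedure tractable at the 100k -> 10k scale the extractor produces.

Importance is the tree's entropy-based impurity decrease; fold accuracy is
recorded per round as a diagnostic but elimination is importance-driven.
Ties in importance are broken by retaining the lower column index, making the
outcome bit-reproducible under a fixed seed.

A single deterministic tree concentrates all importance on the few features
it happens to split on, leaving equally informative features
indistinguishable from noise in that round.  To spread the signal, each fold
fits ``n_tree_seeds`` trees with derived seeds and per-split candidate
subsampling (``max_features``, default sqrt); importances are averaged over
all trees of all folds before elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .datatypes import FeatureTable


def entropy(class_probs) -> float:
    """Shannon entropy −Σ p_i log2 p_i in bits, with 0·log0 := 0.

    The argument must be a probability vector (nonnegative, summing to 1
    within 1e-8).
    """
    p = np.asarray(class_probs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("class_probs must be a non-empty 1-D vector")
    if (p < -1e-12).any():
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"probabilities sum to {p.sum()}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass(frozen=True)
class RFEConfig:
    n_folds: int = 5
    target_n_features: int = 10_000
    step: float = 0.1
    tree_criterion: str = "entropy"
    max_depth: int | None = None
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if not (1 <= self.target_n_features <= n_features):
            raise ValueError(
                f"target_n_features={self.target_n_features} outside "
                f"[1, {n_features}]"
            )
        if not (0 < self.step < 1):
            raise ValueError("step must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class FeatureRanking:
    """Most- to least-important feature ids plus per-round mean fold accuracy."""

    ranked_ids: list[str]
    per_round_accuracy: list[float] = field(default_factory=list)


class TreeRFE:
    """sklearn-style selector: ``fit(X, y)`` then ``transform(X)``.

    Fitted attributes: ``support_`` (boolean retained mask over input
    columns), ``ranked_ids_``/``ranking_`` (importance order),
    ``per_round_accuracy_``.
    """

    def __init__(self, target_n_features: int = 10_000, n_folds: int = 5,
                 step: float = 0.1, tree_criterion: str = "entropy",
                 max_depth: int | None = None, n_tree_seeds: int = 3,
                 max_features: str | float | None = "sqrt",
                 random_state: int = 0):
        self.target_n_features = target_n_features
        self.n_folds = n_folds
        self.step = step
        self.tree_criterion = tree_criterion
        self.max_depth = max_depth
        self.n_tree_seeds = n_tree_seeds
        self.max_features = max_features
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "target_n_features", "n_folds", "step", "tree_criterion",
            "max_depth", "n_tree_seeds", "max_features", "random_state")}

    def set_params(self, **params) -> "TreeRFE":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _round(self, X: np.ndarray, y: np.ndarray, cols: np.ndarray,
               round_no: int) -> tuple[float, np.ndarray]:
        """One elimination round: mean fold accuracy + mean importances.

        Each fold's tree gets its own derived seed so equally-good splits are
        tie-broken differently across folds and rounds; otherwise importance
        collapses onto a single arbitrary member of a tied feature group.
        """
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.random_state)
        accs, imps = [], np.zeros(len(cols))
        n_trees = 0
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            for rep in range(max(1, self.n_tree_seeds)):
                tree_seed = (self.random_state + 7919 * round_no
                             + 104729 * fold + 15485863 * rep) % (2**31 - 1)
                tree = DecisionTreeClassifier(criterion=self.tree_criterion,
                                              max_depth=self.max_depth,
                                              max_features=self.max_features,
                                              random_state=tree_seed)
                tree.fit(X[np.ix_(train_idx, cols)], y[train_idx])
                accs.append(tree.score(X[np.ix_(test_idx, cols)], y[test_idx]))
                imps += tree.feature_importances_
                n_trees += 1
        return float(np.mean(accs)), imps / n_trees

    def fit(self, X, y, feature_ids: list[str] | None = None) -> "TreeRFE":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes for elimination")
        n_features = X.shape[1]
        cfg = RFEConfig(self.n_folds, self.target_n_features, self.step,
                        self.tree_criterion, self.max_depth, self.random_state)
        cfg.validate(n_features)
        ids = feature_ids or [f"f{j}" for j in range(n_features)]

        cols = np.arange(n_features)
        eliminated: list[int] = []  # elimination order, least important first
        accs: list[float] = []
        last_imps = np.zeros(n_features)
        round_no = 0
        while True:
            acc, imps = self._round(X, y, cols, round_no)
            round_no += 1
            accs.append(acc)
            last_imps = imps
            if len(cols) <= self.target_n_features:
                break
            n_drop = max(1, int(np.floor(self.step * len(cols))))
            n_drop = min(n_drop, len(cols) - self.target_n_features)
            # least important first; ties keep the LOWER column index, i.e.
            # among equals the higher index is dropped first
            order = np.lexsort((-cols, imps))
            drop_pos = order[:n_drop]
            eliminated.extend(cols[i] for i in drop_pos)
            keep = np.ones(len(cols), bool)
            keep[drop_pos] = False
            cols = cols[keep]

        retained_order = np.lexsort((cols, -last_imps))  # important first
        ranked_cols = [cols[i] for i in retained_order] + eliminated[::-1]
        self.support_ = np.zeros(n_features, bool)
        self.support_[cols] = True
        self.retained_ids_ = [ids[j] for j in cols]  # input column order
        self.ranked_ids_ = [ids[j] for j in ranked_cols]
        self.ranking_ = FeatureRanking(self.ranked_ids_, accs)
        self.per_round_accuracy_ = accs
        self.feature_ids_in_ = ids
        self.n_features_in_ = n_features
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]

    def fit_transform(self, X, y, feature_ids: list[str] | None = None
                      ) -> np.ndarray:
        return self.fit(X, y, feature_ids).transform(X)


def rfe(table: FeatureTable, cfg: RFEConfig | None = None
        ) -> tuple[FeatureRanking, FeatureTable]:
    """Rank features and return the reduced table (input column order kept)."""
    cfg = cfg or RFEConfig()
    selector = TreeRFE(target_n_features=cfg.target_n_features,
                       n_folds=cfg.n_folds, step=cfg.step,
                       tree_criterion=cfg.tree_criterion,
                       max_depth=cfg.max_depth, random_state=cfg.seed)
    selector.fit(table.matrix, table.labels, table.feature_ids)
    reduced = table.select_columns(selector.retained_ids_)
    return selector.ranking_, reduced
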