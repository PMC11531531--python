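"""Trainable fuzzy deep classifier.

The network combines a dense pathway over all input features with a
fuzzy-rule pathway over a small designated subset of "rule features":

* dense pathway: standardized input -> ReLU -> dense(hidden_dim) -> ReLU;
* rule pathway: for each Wang–Mendel rule i, the firing strength
  α_i = Π_j μ_{ij}(x_j) over the rule features (the fuzzification layer, no
  trainable parameters).  Inside the network each factor is floored at a
  small positive value and the per-sample activations are normalized to sum
  to one (the classic normalized-firing-strength layer of neuro-fuzzy
  systems): with compact-support membership functions the raw conjunctive
  product is identically zero for most unseen samples, which would silence
  the rule pathway exactly where it is needed;
* output: hidden activations and rule activations are concatenated and fed
  to the defuzzification layer β_k = Σ_i α_i w_ik (+ dense-path term and
  bias), followed by a numerically stable softmax.

The rule block of the output weights is initialized from the rule
consequents (one-hot scaled by rule degree) and the dense block at small
scale, so rule knowledge dominates the first epochs and gradient training
refines it; training is Adam on the cross-entropy loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .datatypes import FeatureTable
from .membership import build_partitions
from .rules import RuleBase, prefilter_and_rank, wang_mendel


def relu(x):
    """max(0, x), elementwise."""
    return np.maximum(0.0, x)


def softmax(z) -> np.ndarray:
    """Row-wise softmax, shift-invariant and overflow-safe."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def fuzzify(X_rule, rule_base: RuleBase, floor: float = 0.0) -> np.ndarray:
    """Per-rule firing strengths α_si = Π_j μ at the rule's antecedent level.

    ``X_rule`` holds only the rule features, in rule-base partition order.
    Returns an (n_samples, n_rules) array with entries in [0, 1].

    With compact-support membership kinds the plain product is exactly zero
    for any sample more than one level away from a rule in ANY variable —
    in several dimensions that is almost every unseen sample.  ``floor``
    clips each factor from below (e.g. 1e-3) so activations stay positive
    and rankable: rules violated in fewer variables still fire strictly
    harder.  The default 0 keeps the plain product semantics.
    """
    X_rule = np.atleast_2d(np.asarray(X_rule, dtype=float))
    if X_rule.shape[1] != len(rule_base.partitions):
        raise ValueError("sample width must match the rule-base partitions")
    ants = np.array([r.antecedent for r in rule_base.rules])  # (M, J)
    alpha = np.ones((X_rule.shape[0], len(rule_base.rules)))
    for j, part in enumerate(rule_base.partitions):
        mu = part.memberships(X_rule[:, j])  # (n, L)
        alpha *= np.maximum(mu[:, ants[:, j]], floor)
    return alpha


def defuzzify(alpha, w) -> np.ndarray:
    """Class scores β_sk = Σ_i α_si w_ik (a plain matrix product)."""
    alpha = np.asarray(alpha, dtype=float)
    w = np.asarray(w, dtype=float)
    if alpha.shape[-1] != w.shape[0]:
        raise ValueError(
            f"activation width {alpha.shape[-1]} != weight rows {w.shape[0]}")
    return alpha @ w


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    loss: str = "cross_entropy"
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    train_fraction: float = 0.8

    def validate(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "cross_entropy":
            raise ValueError("only cross-entropy loss is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")


class FuzzyDeepClassifier(BaseEstimator, ClassifierMixin):
    """Neuro-fuzzy classifier with a Wang–Mendel fuzzification layer.

    Parameters mirror the training recipe: Adam, learning rate 1e-3,
    cross-entropy, batch size 32, 100 epochs, internal stratified 80/20
    train/validation split.  When no ``rule_base`` is supplied, one is
    induced during ``fit`` from the training split: the ``top_k_rule_features``
    columns best correlated with the label (after dropping columns with more
    than ``zero_frac_threshold`` exact zeros) are partitioned into
    ``n_levels`` fuzzy levels and passed through Wang–Mendel induction.

    Fitted attributes include ``classes_``, ``rule_base_``,
    ``rule_feature_indices_``, ``history_`` (per-epoch train/validation loss
    and accuracy) and the trained weight matrices.
    """

    def __init__(self, hidden_dim: int = 128, n_levels: int = 9,
                 mf_kind: str = "triangular", placement: str = "uniform",
                 top_k_rule_features: int = 8,
                 zero_frac_threshold: float = 0.10,
                 learning_rate: float = 0.001, batch_size: int = 32,
                 epochs: int = 100, validation_fraction: float = 0.2,
                 activation_floor: float = 1e-3,
                 normalize_firing: bool = True,
                 rule_base: RuleBase | None = None,
                 rule_feature_indices: list[int] | None = None,
                 random_state: int = 0):
        self.hidden_dim = hidden_dim
        self.n_levels = n_levels
        self.mf_kind = mf_kind
        self.placement = placement
        self.top_k_rule_features = top_k_rule_features
        self.zero_frac_threshold = zero_frac_threshold
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.activation_floor = activation_floor
        self.normalize_firing = normalize_firing
        self.rule_base = rule_base
        self.rule_feature_indices = rule_feature_indices
        self.random_state = random_state

    # ------------------------------------------------------------------ rules
    def _induce_rules(self, X, y, feature_ids):
        table = FeatureTable(X, y, feature_ids)
        k = min(self.top_k_rule_features, X.shape[1])
        ranked = prefilter_and_rank(table, self.zero_frac_threshold, k,
                                    seed=self.random_state)
        cols = [feature_ids.index(fid) for fid in ranked.feature_ids]
        parts = build_partitions(X[:, cols], ranked.feature_ids,
                                 n_levels=self.n_levels, mf_kind=self.mf_kind,
                                 placement=self.placement,
                                 seed=self.random_state)
        return wang_mendel(X[:, cols], y, parts), cols

    # ---------------------------------------------------------------- network
    def _rule_activations(self, X: np.ndarray) -> np.ndarray:
        """Floored, optionally row-normalized firing strengths for raw X."""
        alpha = fuzzify(X[:, self.rule_feature_indices_], self.rule_base_,
                        floor=self.activation_floor)
        if self.normalize_firing:
            s = alpha.sum(axis=1, keepdims=True)
            alpha = np.divide(alpha, s, out=np.zeros_like(alpha), where=s > 0)
        return alpha

    def _forward(self, Xs, alpha):
        h0 = relu(Xs)
        z1 = h0 @ self.W1_ + self.b1_
        h1 = relu(z1)
        beta = h1 @ self.W3h_ + defuzzify(alpha, self.W3r_) + self.b3_
        return h0, z1, h1, softmax(beta)

    def _loss(self, proba, y_idx):
        eps = 1e-12
        return float(-np.log(proba[np.arange(len(y_idx)), y_idx] + eps).mean())

    def fit(self, X, y, feature_ids: list[str] | None = None
            ) -> "FuzzyDeepClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes to train")
        ids = feature_ids or [f"f{j}" for j in range(X.shape[1])]
        rng = np.random.default_rng(self.random_state)

        idx_tr, idx_val = train_test_split(
            np.arange(len(y)), test_size=self.validation_fraction,
            stratify=y_idx, random_state=self.random_state)
        if len(np.unique(y_idx[idx_tr])) < 2:
            raise ValueError("training split contains a single class")
        self.train_indices_, self.val_indices_ = idx_tr, idx_val
        Xtr, ytr = X[idx_tr], y_idx[idx_tr]
        Xval, yval = X[idx_val], y_idx[idx_val]

        # rule pathway: induced on the training split only
        if self.rule_base is not None:
            self.rule_base_ = self.rule_base
            if self.rule_feature_indices is None:
                raise ValueError(
                    "rule_feature_indices must accompany a precomputed rule_base")
            self.rule_feature_indices_ = list(self.rule_feature_indices)
        else:
            self.rule_base_, self.rule_feature_indices_ = self._induce_rules(
                Xtr, ytr, ids)
        self.feature_ids_in_ = ids
        self.n_features_in_ = X.shape[1]

        # dense-path standardization (rule path sees raw values)
        self.x_mean_ = Xtr.mean(axis=0)
        self.x_std_ = np.where(Xtr.std(axis=0) > 1e-12, Xtr.std(axis=0), 1.0)

        d, h = X.shape[1], self.hidden_dim
        M, K = self.rule_base_.n_rules, len(self.classes_)
        self.W1_ = rng.normal(0, np.sqrt(2.0 / d), size=(d, h))
        self.b1_ = np.zeros(h)
        self.W3h_ = rng.normal(0, 0.1 / np.sqrt(h), size=(h, K))
        # one-hot consequents scaled by relative rule degree; the global
        # 1/mean(degree) factor puts the rule-path scores at O(1) so the
        # randomly initialized dense path cannot drown them at epoch 0
        self.W3r_ = np.zeros((M, K))
        degrees = np.array([r.degree for r in self.rule_base_.rules])
        rel = degrees / degrees.mean() if degrees.size else degrees
        for i, r in enumerate(self.rule_base_.rules):
            k = int(np.searchsorted(self.classes_, r.consequent)) \
                if r.consequent in self.classes_ else 0
            self.W3r_[i, k] = rel[i]
        self.b3_ = np.zeros(K)

        alpha_tr = self._rule_activations(Xtr)
        alpha_val = self._rule_activations(Xval)
        Xtr_s = (Xtr - self.x_mean_) / self.x_std_
        Xval_s = (Xval - self.x_mean_) / self.x_std_

        params = ["W1_", "b1_", "W3h_", "W3r_", "b3_"]
        m_t = {p: np.zeros_like(getattr(self, p)) for p in params}
        v_t = {p: np.zeros_like(getattr(self, p)) for p in params}
        beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
        step = 0
        n_tr = len(ytr)
        self.history_ = {"train_loss": [], "val_loss": [],
                         "train_accuracy": [], "val_accuracy": []}
        for _ in range(self.epochs):
            order = rng.permutation(n_tr)
            for start in range(0, n_tr, self.batch_size):
                b = order[start:start + self.batch_size]
                xb, ab, yb = Xtr_s[b], alpha_tr[b], ytr[b]
                h0, z1, h1, proba = self._forward(xb, ab)
                if not np.isfinite(proba).all():
                    raise RuntimeError(
                        "non-finite network output during training; lower the "
                        "learning rate or check the input scale")
                # cross-entropy + softmax gradient
                g_beta = proba.copy()
                g_beta[np.arange(len(yb)), yb] -= 1.0
                g_beta /= len(yb)
                grads = {
                    "W3h_": h1.T @ g_beta,
                    "W3r_": ab.T @ g_beta,
                    "b3_": g_beta.sum(axis=0),
                }
                g_h1 = (g_beta @ self.W3h_.T) * (z1 > 0)
                grads["W1_"] = h0.T @ g_h1
                grads["b1_"] = g_h1.sum(axis=0)
                step += 1
                for p in params:
                    g = grads[p]
                    m_t[p] = beta1 * m_t[p] + (1 - beta1) * g
                    v_t[p] = beta2 * v_t[p] + (1 - beta2) * g**2
                    m_hat = m_t[p] / (1 - beta1**step)
                    v_hat = v_t[p] / (1 - beta2**step)
                    setattr(self, p, getattr(self, p)
                            - self.learning_rate * m_hat
                            / (np.sqrt(v_hat) + eps_adam))
            for name, (xs, al, yy) in {
                "train": (Xtr_s, alpha_tr, ytr),
                "val": (Xval_s, alpha_val, yval),
            }.items():
                proba = self._forward(xs, al)[-1]
                if not np.isfinite(proba).all():
                    raise RuntimeError("non-finite loss after epoch")
                self.history_[f"{name}_loss"].append(self._loss(proba, yy))
                self.history_[f"{name}_accuracy"].append(
                    float((proba.argmax(axis=1) == yy).mean()))
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature columns, "
                f"got {X.shape[1] if X.ndim == 2 else 'non-2D input'}")
        alpha = self._rule_activations(X)
        return self._forward((X - self.x_mean_) / self.x_std_, alpha)[-1]

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def train(table: FeatureTable, rule_base: RuleBase | None = None,
          cfg: TrainConfig | None = None,
          rule_feature_indices: list[int] | None = None, **model_kwargs
          ) -> tuple[FuzzyDeepClassifier, dict]:
    """Fit a :class:`FuzzyDeepClassifier` on a feature table.

    Returns the model plus its per-epoch history (train/validation loss and
    accuracy).  The table is split stratified into train and validation
    parts according to ``cfg.train_fraction``.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    model = FuzzyDeepClassifier(
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        epochs=cfg.epochs, validation_fraction=1.0 - cfg.train_fraction,
        rule_base=rule_base, rule_feature_indices=rule_feature_indices,
        random_state=cfg.seed, **model_kwargs)
    model.fit(table.matrix, table.labels, table.feature_ids)
    return model, model.history_


def predict(model: FuzzyDeepClassifier, table: FeatureTable
            ) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and hard labels for every row of the table."""
    proba = model.predict_proba(table.matrix)
    return proba, model.classes_[proba.argmax(axis=1)]
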