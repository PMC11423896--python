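"""Sparse linear category readout over frozen features.

A multinomial linear classifier trained with minibatch SGD on cross-entropy
plus an L1 penalty on the weights, optimized with proximal (soft-threshold)
steps under a one-cycle learning-rate schedule. The backbone that produced
the features is never touched; only the readout weights and biases learn.

``SparseLinearReadout`` follows the scikit-learn estimator protocol
(``fit`` / ``predict`` / ``decision_function``, ``get_params``, fitted
attributes with trailing underscores) and composes with sklearn model
selection; ``train_sparse_readout`` is the thin functional wrapper the
pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

#: weights below this magnitude count as zero in the sparsity report
SPARSITY_CUTOFF = 1e-3


@dataclass
class ReadoutConfig:
    l1_lambda: float = 5e-3
    epochs: int = 250
    batch_size: int = 64
    max_lr: float = 0.05
    initial_lr: float = 0.001
    pct_start: float = 0.3
    k: int = 1           # top-k used by downstream accuracy metrics
    seed: int = 0

    def validate(self) -> None:
        if self.l1_lambda < 0:
            raise ValueError("l1_lambda must be >= 0")
        if not 0.0 < self.pct_start < 1.0:
            raise ValueError("pct_start must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def one_cycle_lr(step: int, total_steps: int, max_lr: float, initial_lr: float,
                 pct_start: float) -> float:
    """Linear warm-up to ``max_lr`` then cosine anneal back down."""
    up = max(int(round(pct_start * total_steps)), 1)
    if step < up:
        return initial_lr + (max_lr - initial_lr) * step / up
    down = max(total_steps - up, 1)
    frac = (step - up) / down
    final_lr = initial_lr / 25.0
    return final_lr + 0.5 * (max_lr - final_lr) * (1.0 + np.cos(np.pi * frac))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SparseLinearReadout(BaseEstimator, ClassifierMixin):
    """L1-regularized multinomial readout trained by proximal SGD.

    Parameters mirror :class:`ReadoutConfig`; the L1 penalty applies to the
    weights only (biases are unpenalized), via a soft-threshold proximal
    step after each gradient update.
    """

    def __init__(self, l1_lambda: float = 1e-5, epochs: int = 10,
                 batch_size: int = 64, max_lr: float = 0.05,
                 initial_lr: float = 0.001, pct_start: float = 0.3,
                 random_state: int = 0):
        self.l1_lambda = l1_lambda
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_lr = max_lr
        self.initial_lr = initial_lr
        self.pct_start = pct_start
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SparseLinearReadout":
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        if self.l1_lambda < 0:
            raise ValueError("l1_lambda must be >= 0")
        if not 0.0 < self.pct_start < 1.0:
            raise ValueError("pct_start must be in (0, 1)")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        c = len(self.classes_)
        if c < 2:
            raise ValueError("need >= 2 categories")
        counts = np.bincount(y_idx, minlength=c)
        if counts.min() < 2:
            raise ValueError("each category needs >= 2 training stimuli")

        rng = np.random.default_rng(self.random_state)
        w = 0.01 * rng.standard_normal((c, p))
        b = np.zeros(c)
        onehot = np.eye(c)[y_idx]

        bs = min(self.batch_size, n)
        batches_per_epoch = int(np.ceil(n / bs))
        total_steps = self.epochs * batches_per_epoch
        step = 0
        log = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                xb, tb = X[idx], onehot[idx]
                probs = _softmax(xb @ w.T + b)
                lr = one_cycle_lr(step, total_steps, self.max_lr,
                                  self.initial_lr, self.pct_start)
                grad_w = (probs - tb).T @ xb / len(idx)
                grad_b = (probs - tb).mean(axis=0)
                w -= lr * grad_w
                b -= lr * grad_b
                # proximal L1 step on weights only
                if self.l1_lambda > 0:
                    thr = lr * self.l1_lambda
                    w = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
                eps = 1e-12
                epoch_loss += -np.log(
                    np.maximum((probs * tb).sum(axis=1), eps)
                ).sum()
                step += 1
            log.append(epoch_loss / n)

        self.coef_ = w
        self.intercept_ = b
        self.training_log_ = np.asarray(log)
        self.sparsity_fraction_ = float(np.mean(np.abs(w) < SPARSITY_CUTOFF))
        self.n_features_in_ = p
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_.T + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.decision_function(X))


@dataclass
class ReadoutHead:
    """Trained readout: category x feature weights, biases, and provenance."""

    weights: np.ndarray
    bias: np.ndarray
    classes: np.ndarray
    sparsity_fraction: float
    training_log: np.ndarray
    config: ReadoutConfig = field(default_factory=ReadoutConfig)

    def scores(self, features: np.ndarray) -> np.ndarray:
        return features @ self.weights.T + self.bias


def train_sparse_readout(
    features: np.ndarray, labels: np.ndarray, config: ReadoutConfig
) -> ReadoutHead:
    """Fit the sparse readout on penultimate-stage features."""
    config.validate()
    est = SparseLinearReadout(
        l1_lambda=config.l1_lambda,
        epochs=config.epochs,
        batch_size=config.batch_size,
        max_lr=config.max_lr,
        initial_lr=config.initial_lr,
        pct_start=config.pct_start,
        random_state=config.seed,
    ).fit(features, labels)
    return ReadoutHead(
        weights=est.coef_,
        bias=est.intercept_,
        classes=est.classes_,
        sparsity_fraction=est.sparsity_fraction_,
        training_log=est.training_log_,
        config=config,
    )


def topk_accuracy_per_category(
    head: ReadoutHead, features: np.ndarray, labels: np.ndarray, k: int
) -> dict[str, float]:
    """Fraction of each category's stimuli with the true label in the top k.

    Score ties are broken deterministically by ascending category index.
    """
    labels = np.asarray(labels)
    classes = list(head.classes)
    if k > len(classes):
        raise ValueError(f"k={k} exceeds number of categories ({len(classes)})")
    scores = head.scores(features)
    # stable sort on -score keeps ascending class index among ties
    order = np.argsort(-scores, axis=1, kind="stable")
    topk = order[:, :k]
    y_idx = np.array([classes.index(l) for l in labels])
    hit = (topk == y_idx[:, None]).any(axis=1)
    return {
        cat: float(hit[labels == cat].mean())
        for cat in classes
        if (labels == cat).any()
    }
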