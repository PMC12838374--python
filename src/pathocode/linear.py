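"""Seeded multinomial softmax regression trained with AdamW.

Shared optimization core for the reference token tagger and the per
terminology code classifiers.  Deliberately small: a single linear layer
trained by minibatch AdamW on the masked cross-entropy loss, with an
optional validation set for early stopping.  Everything (shuffling,
initialization) derives from one integer seed, so training is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import IGNORE_INDEX
from .encoders import cross_entropy, softmax


@dataclass
class TrainConfig:
    """Optimizer settings; defaults mirror a short fine-tuning recipe
    (3 epochs, batch 8, weight decay 0.01) with the learning rate scaled
    to a linear model trained from scratch."""

    epochs: int = 3
    learning_rate: float = 0.05
    batch_size: int = 8
    weight_decay: float = 0.01
    seed: int = 0
    patience: int | None = None  # early stop after this many non-improving epochs


class SoftmaxRegression:
    """Linear classifier W x + b with softmax output, AdamW updates."""

    def __init__(self, config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        self.W: np.ndarray | None = None
        self.b: np.ndarray | None = None
        self.classes_: np.ndarray | None = None
        self.history_: list[float] = []
        self.stopped_epoch_: int | None = None

    # -- AdamW machinery ---------------------------------------------------

    def _init_state(self, n_features: int, n_classes: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_features, n_classes)) * 0.01).astype(np.float64)
        self.b = np.zeros(n_classes, dtype=np.float64)
        self._m = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._v = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._t = 0

    def _step(self, gW: np.ndarray, gb: np.ndarray) -> None:
        cfg = self.config
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self._t += 1
        for i, (param, grad) in enumerate(((self.W, gW), (self.b, gb))):
            self._m[i] = beta1 * self._m[i] + (1 - beta1) * grad
            self._v[i] = beta2 * self._v[i] + (1 - beta2) * grad**2
            m_hat = self._m[i] / (1 - beta1**self._t)
            v_hat = self._v[i] / (1 - beta2**self._t)
            update = cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            if i == 0:  # decoupled weight decay on W only
                update = update + cfg.learning_rate * cfg.weight_decay * param
            param -= update

    # -- public API --------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "SoftmaxRegression":
        """Train on rows of X with integer labels y; -100 labels are dropped
        before training (invisible to loss and fitted state).

        With a validation set and ``patience`` set, training stops once the
        validation loss has failed to improve for ``patience`` consecutive
        epochs.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        keep = y != IGNORE_INDEX
        X, y = X[keep], y[keep]
        if X.shape[0] == 0:
            raise ValueError("empty training set after masking")
        self.classes_ = np.unique(y)
        n_classes = int(self.classes_.max()) + 1
        if y_val is not None and len(y_val):
            # the validation fold may hold labels unseen in training
            n_classes = max(n_classes, int(np.max(y_val)) + 1)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self._init_state(X.shape[1], n_classes, rng)

        best_val = np.inf
        bad_epochs = 0
        best_params: tuple[np.ndarray, np.ndarray] | None = None
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb, yb = X[idx], y[idx]
                probs = softmax(Xb @ self.W + self.b, axis=-1)
                grad_logits = probs
                grad_logits[np.arange(len(yb)), yb] -= 1.0
                grad_logits /= len(yb)
                self._step(Xb.T @ grad_logits, grad_logits.sum(axis=0))
            self.history_.append(self._loss(X, y))
            if X_val is not None and cfg.patience is not None:
                val_loss = self._loss(np.asarray(X_val, float), np.asarray(y_val, int))
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    bad_epochs = 0
                    best_params = (self.W.copy(), self.b.copy())
                else:
                    bad_epochs += 1
                    if bad_epochs >= cfg.patience:
                        self.stopped_epoch_ = epoch + 1
                        break
        if best_params is not None:
            self.W, self.b = best_params
        return self

    def _loss(self, X: np.ndarray, y: np.ndarray) -> float:
        return cross_entropy(y, self.predict_proba(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.W is None:
            raise RuntimeError("model is not trained")
        return softmax(np.asarray(X, dtype=np.float64) @ self.W + self.b, axis=-1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=-1)
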