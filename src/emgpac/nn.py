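"""Feedforward binary classifier: 4 hidden ReLU layers of 128 units,
dropout 0.2 after each hidden layer, sigmoid output, binary cross-entropy
loss, Adam (lr 1e-3), batch size 32, 20 epochs.

Implemented directly on NumPy so that the architecture matches the
specification exactly (including dropout) and training is bit-reproducible
from a seed in single-threaded runs.  He-uniform initialisation for the
ReLU stack; inverted dropout (activations scaled by 1/(1-p) at train
time) so inference needs no rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FNNSpec", "FNN"]


@dataclass(frozen=True)
class FNNSpec:
    """Architecture and training hyper-parameters."""

    hidden_layers: int = 4
    width: int = 128
    dropout: float = 0.2
    batch_size: int = 32
    epochs: int = 20
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def validate(self):
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.hidden_layers < 1 or self.width < 1:
            raise ValueError("need at least one hidden unit/layer")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class FNN:
    """The feedforward net.  ``fit`` trains for exactly ``spec.epochs``."""

    def __init__(self, n_features: int, spec: FNNSpec = FNNSpec(),
                 seed: int | None = None):
        spec.validate()
        self.spec = spec
        self.n_features = n_features
        self.rng = np.random.default_rng(spec.seed if seed is None else seed)
        dims = [n_features] + [spec.width] * spec.hidden_layers + [1]
        # float32 throughout: halves the BLAS cost of the many small
        # batch-32 matmuls without affecting determinism
        self.weights, self.biases = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / d_in)  # He-uniform
            self.weights.append(
                self.rng.uniform(-bound, bound, size=(d_in, d_out)).astype(np.float32))
            self.biases.append(np.zeros(d_out, dtype=np.float32))
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0
        self.history: dict = {}

    # ------------------------------------------------------------------
    def _forward(self, X, train: bool):
        """Returns activations per layer and dropout masks."""
        acts = [X]
        masks = []
        a = X
        p = self.spec.dropout
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, np.float32(0.0))
            if train and p > 0:
                mask = ((self.rng.random(a.shape) >= p) / (1.0 - p)).astype(np.float32)
                a = a * mask
            else:
                mask = None
            masks.append(mask)
            acts.append(a)
        z = a @ self.weights[-1] + self.biases[-1]
        prob = _sigmoid(z)
        acts.append(prob)
        return acts, masks

    def _adam_step(self, grads):
        s = self.spec
        self._adam_t += 1
        bc1 = 1.0 - s.beta1**self._adam_t
        bc2 = 1.0 - s.beta2**self._adam_t
        params = self.weights + self.biases
        for i, (p, g) in enumerate(zip(params, grads)):
            m, v = self._adam_m[i], self._adam_v[i]
            m *= s.beta1
            m += (1 - s.beta1) * g
            v *= s.beta2
            v += (1 - s.beta2) * np.square(g)
            p -= (s.learning_rate / bc1) * m / (np.sqrt(v / bc2) + s.eps)

    def _batch_update(self, X, y):
        acts, masks = self._forward(X, train=True)
        prob = acts[-1][:, 0]
        m = len(y)
        # d BCE / d z for sigmoid output
        delta = ((prob - y) / m)[:, None]
        w_grads = [None] * len(self.weights)
        b_grads = [None] * len(self.biases)
        for layer in range(len(self.weights) - 1, -1, -1):
            a_prev = acts[layer]
            w_grads[layer] = a_prev.T @ delta
            b_grads[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.weights[layer].T
                if masks[layer - 1] is not None:
                    delta = delta * masks[layer - 1]
                delta = delta * (acts[layer] > 0)
        self._adam_step(w_grads + b_grads)

    # ------------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train for exactly ``spec.epochs`` passes over (X, y)."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if set(np.unique(y).astype(float)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training data contain a single class")
        n = len(y)
        bs = self.spec.batch_size
        for _ in range(self.spec.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                self._batch_update(X[idx], y[idx])
        self.history = {"train_accuracy": self.accuracy(X, y)}
        if X_val is not None and len(X_val):
            self.history["val_accuracy"] = self.accuracy(X_val, y_val)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-row probability of the positive (case) class, in (0, 1)."""
        X = np.asarray(X, dtype=np.float32)
        acts, _ = self._forward(X, train=False)
        eps = 1e-7
        return np.clip(acts[-1][:, 0].astype(float), eps, 1 - eps)

    def accuracy(self, X, y, threshold: float = 0.5) -> float:
        return float(np.mean((self.predict_proba(X) >= threshold) == (np.asarray(y) == 1)))

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "spec": self.spec.__dict__,
            "n_features": self.n_features,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
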