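"""Minimal fully connected regression network on numpy.

ELU activations, inverted dropout, Adam, and a mean-Euclidean-distance loss
(the distance between predicted and true standardized coordinates), with
early stopping on a held-out validation set.  Deterministic given the
generator passed in.
"""

from __future__ import annotations

import numpy as np


def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x, fx):
    return np.where(x > 0, 1.0, fx + 1.0)


class MLPRegressorNP:
    def __init__(
        self,
        n_in: int,
        n_out: int,
        hidden: tuple[int, ...] = (128, 128),
        dropout: float = 0.25,
        learning_rate: float = 1e-3,
        max_epochs: int = 300,
        patience: int = 20,
        batch_size: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.lr = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        rng = rng if rng is not None else np.random.default_rng()
        sizes = [n_in, *self.hidden, n_out]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1])) for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._rng = rng

    # -- forward / backward -------------------------------------------------
    def _forward(self, X, train: bool):
        acts = [X]
        pre = []
        masks = []
        h = X
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            pre.append(z)
            if i < n_layers - 1:
                h = _elu(z)
                if train and self.dropout > 0:
                    m = (self._rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * m
                    masks.append(m)
                else:
                    masks.append(None)
            else:
                h = z
            acts.append(h)
        return acts, pre, masks

    @staticmethod
    def _loss_grad(yhat, y):
        diff = yhat - y
        d = np.sqrt((diff**2).sum(axis=1))
        loss = d.mean()
        safe = np.maximum(d, 1e-12)[:, None]
        grad = diff / safe / y.shape[0]
        return loss, grad

    def fit(self, X, y, X_val=None, y_val=None):
        n = X.shape[0]
        bs = self.batch_size or n
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best = None
        stall = 0
        for _epoch in range(self.max_epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                acts, pre, masks = self._forward(X[idx], train=True)
                loss, g = self._loss_grad(acts[-1], y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
                grads_W = [None] * len(self.W)
                grads_b = [None] * len(self.W)
                delta = g
                for i in range(len(self.W) - 1, -1, -1):
                    grads_W[i] = acts[i].T @ delta
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.W[i].T
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                        delta = delta * _elu_grad(pre[i - 1], _elu(pre[i - 1]))
                t += 1
                for i in range(len(self.W)):
                    for g_, p, m_, v_ in ((grads_W[i], self.W, mW, vW), (grads_b[i], self.b, mb, vb)):
                        m_[i] = b1 * m_[i] + (1 - b1) * g_
                        v_[i] = b2 * v_[i] + (1 - b2) * g_**2
                        mhat = m_[i] / (1 - b1**t)
                        vhat = v_[i] / (1 - b2**t)
                        p[i] = p[i] - self.lr * mhat / (np.sqrt(vhat) + eps)
            if X_val is not None and X_val.shape[0] > 0:
                val_loss = self._loss_grad(self.predict(X_val), y_val)[0]
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best is not None:
            self.W, self.b = best
        self.best_val_loss_ = best_val if best is not None else np.nan
        return self

    def predict(self, X):
        acts, _, _ = self._forward(X, train=False)
        return acts[-1]
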