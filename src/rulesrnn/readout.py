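"""Recurrent sequence classifier for population decoding.

A compact two-layer LSTM with a logistic readout, trained by BPTT with Adam,
inverted dropout (p = 0.2) between the layers and L2 weight decay (1e-3).
It reads PCA-reduced, time-binned population spike counts and predicts the
trial's rule; accuracy can be queried at every prefix of the delay period to
show how rule information accumulates over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class _LSTMLayer:
    def __init__(self, d_in: int, d_hid: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(d_in + d_hid)
        self.W = rng.uniform(-s, s, size=(4 * d_hid, d_in + d_hid))
        self.b = np.zeros(4 * d_hid)
        self.b[d_hid : 2 * d_hid] = 1.0     # forget-gate bias
        self.d_in, self.d_hid = d_in, d_hid

    def forward(self, X: np.ndarray):
        """X: (B, T, d_in) -> H: (B, T, d_hid) plus cached gates."""
        B, T, _ = X.shape
        H = self.d_hid
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        Hs = np.empty((B, T, H))
        for t in range(T):
            z = np.concatenate([X[:, t], h], axis=1)
            a = z @ self.W.T + self.b
            i, f, o, g = (_sigmoid(a[:, :H]), _sigmoid(a[:, H:2*H]),
                          _sigmoid(a[:, 2*H:3*H]), np.tanh(a[:, 3*H:]))
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            Hs[:, t] = h
            cache.append((z, i, f, o, g, c.copy(), tc))
        self._cache = cache
        return Hs

    def backward(self, dHs: np.ndarray):
        """dHs: (B, T, d_hid) upstream grads; returns (dX, dW, db)."""
        B, T, H = dHs.shape
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dX = np.empty((B, T, self.d_in))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            z, i, f, o, g, c, tc = self._cache[t]
            dh = dHs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di, dg = dc * g, dc * i
            c_prev = self._cache[t - 1][5] if t > 0 else np.zeros_like(c)
            df = dc * c_prev
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                 dg * (1 - g**2)], axis=1)
            dW += da.T @ z
            db += da.sum(axis=0)
            dz = da @ self.W
            dX[:, t] = dz[:, : self.d_in]
            dh_next = dz[:, self.d_in:]
            dc_next = dc * f
        return dX, dW, db


@dataclass
class FitInfo:
    losses: list


class LSTMClassifier:
    """Two stacked LSTM layers + logistic output on the final hidden state."""

    def __init__(self, n_features: int, hidden: int = 16, dropout: float = 0.2,
                 l2: float = 1e-3, lr: float = 0.01, epochs: int = 60,
                 seed: int = 0):
        self.hidden, self.dropout, self.l2 = hidden, dropout, l2
        self.lr, self.epochs = lr, epochs
        self.rng = np.random.default_rng(seed)
        self.l1 = _LSTMLayer(n_features, hidden, self.rng)
        self.l2_layer = _LSTMLayer(hidden, hidden, self.rng)
        self.w_out = self.rng.normal(0, 0.1, size=hidden)
        self.b_out = 0.0

    def _params(self):
        return [("W1", self.l1, "W"), ("b1", self.l1, "b"),
                ("W2", self.l2_layer, "W"), ("b2", self.l2_layer, "b")]

    def fit(self, X: np.ndarray, y: np.ndarray) -> FitInfo:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        mom = {}
        losses = []
        for ep in range(self.epochs):
            H1 = self.l1.forward(X)
            if self.dropout > 0:
                mask = (self.rng.random(H1.shape) >= self.dropout) / (1 - self.dropout)
                H1d = H1 * mask
            else:
                mask = None
                H1d = H1
            H2 = self.l2_layer.forward(H1d)
            hT = H2[:, -1]
            p = _sigmoid(hT @ self.w_out + self.b_out)
            eps = 1e-12
            loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            losses.append(float(loss))

            dlogit = (p - y) / len(y)
            dw_out = hT.T @ dlogit + self.l2 * self.w_out
            db_out = dlogit.sum()
            dH2 = np.zeros_like(H2)
            dH2[:, -1] = np.outer(dlogit, self.w_out)
            dH1d, dW2, db2 = self.l2_layer.backward(dH2)
            if mask is not None:
                dH1d = dH1d * mask
            _, dW1, db1 = self.l1.backward(dH1d)
            grads = {"W1": dW1 + self.l2 * self.l1.W, "b1": db1,
                     "W2": dW2 + self.l2 * self.l2_layer.W, "b2": db2,
                     "w_out": dw_out, "b_out": db_out}
            for name, layer, attr in self._params():
                self._adam(mom, name, getattr(layer, attr), grads[name])
            self._adam(mom, "w_out", self.w_out, grads["w_out"])
            self.b_out -= self.lr * grads["b_out"]
        return FitInfo(losses=losses)

    def _adam(self, mom, name, param, grad, b1=0.9, b2=0.999, eps=1e-8):
        m, v, t = mom.get(name, (0.0, 0.0, 0))
        t += 1
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad**2
        mom[name] = (m, v, t)
        step = self.lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
        param -= step

    def predict_proba(self, X: np.ndarray, prefix: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if prefix is not None:
            X = X[:, :prefix]
        H1 = self.l1.forward(X)
        H2 = self.l2_layer.forward(H1)
        return _sigmoid(H2[:, -1] @ self.w_out + self.b_out)

    def predict(self, X: np.ndarray, prefix: int | None = None,
                threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X, prefix) >= threshold).astype(int)
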