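"""A small bidirectional LSTM sequence classifier in pure numpy.

Sized for this package's problem: sequences of ~100 steps x 3 latent
dimensions, tens of training trials, 4 output classes.  Architecture: one
bidirectional LSTM layer (final hidden state of each direction,
concatenated) followed by a dense softmax layer; trained full-batch with
Adam on the cross-entropy.  Gradients are exact backpropagation through
time and are covered by a numerical gradient check in the test suite.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _init_direction(rng: np.random.Generator, n_in: int, n_hidden: int):
    k_x = np.sqrt(6.0 / (n_in + 4 * n_hidden))
    k_h = np.sqrt(6.0 / (n_hidden + 4 * n_hidden))
    wx = rng.uniform(-k_x, k_x, size=(n_in, 4 * n_hidden))
    wh = rng.uniform(-k_h, k_h, size=(n_hidden, 4 * n_hidden))
    b = np.zeros(4 * n_hidden)
    b[n_hidden:2 * n_hidden] = 1.0          # forget-gate bias
    return {"wx": wx, "wh": wh, "b": b}


def _lstm_forward(xs: np.ndarray, p: dict):
    """xs: (T, B, I) -> final hidden (B, H) plus the BPTT cache."""
    t_len, batch, _ = xs.shape
    n_hidden = p["wh"].shape[0]
    h = np.zeros((batch, n_hidden))
    c = np.zeros((batch, n_hidden))
    cache = []
    for t in range(t_len):
        z = xs[t] @ p["wx"] + h @ p["wh"] + p["b"]
        i = _sigmoid(z[:, :n_hidden])
        f = _sigmoid(z[:, n_hidden:2 * n_hidden])
        g = np.tanh(z[:, 2 * n_hidden:3 * n_hidden])
        o = _sigmoid(z[:, 3 * n_hidden:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        cache.append((xs[t], h, c, i, f, g, o, tc))
        h = o * tc
        c = c_new
    return h, cache


def _lstm_backward(dh_final: np.ndarray, cache: list, p: dict):
    n_hidden = p["wh"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for x, h_prev, c_prev, i, f, g, o, tc in reversed(cache):
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ], axis=1)
        grads["wx"] += x.T @ dz
        grads["wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dh = dz @ p["wh"].T
        dc = dc * f
    return grads


class BiLSTMClassifier:
    """Bidirectional LSTM classifier for (n, T, d) sequences.

    Parameters mirror the reference decoder: 3 inputs, 20 hidden units per
    direction, 4 softmax classes, Adam at learning rate 0.01, full batch.
    """

    def __init__(self, n_hidden: int = 20, n_classes: int = 4,
                 epochs: int = 150, learning_rate: float = 0.01,
                 seed: int | np.random.Generator = 0):
        self.n_hidden = n_hidden
        self.n_classes = n_classes
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.rng = (seed if isinstance(seed, np.random.Generator)
                    else np.random.default_rng(seed))
        self.params: dict | None = None

    # -- internals -------------------------------------------------------
    def _init_params(self, n_in: int) -> dict:
        rng = self.rng
        fwd = _init_direction(rng, n_in, self.n_hidden)
        bwd = _init_direction(rng, n_in, self.n_hidden)
        k = np.sqrt(6.0 / (2 * self.n_hidden + self.n_classes))
        return {
            **{f"f_{k_}": v for k_, v in fwd.items()},
            **{f"b_{k_}": v for k_, v in bwd.items()},
            "wo": rng.uniform(-k, k, size=(2 * self.n_hidden, self.n_classes)),
            "bo": np.zeros(self.n_classes),
        }

    @staticmethod
    def _split(params: dict, prefix: str) -> dict:
        return {k[2:]: v for k, v in params.items() if k.startswith(prefix)}

    def _forward(self, xs: np.ndarray, params: dict):
        """xs: (T, B, d).  Returns class probabilities and caches."""
        h_f, cache_f = _lstm_forward(xs, self._split(params, "f_"))
        h_b, cache_b = _lstm_forward(xs[::-1], self._split(params, "b_"))
        feats = np.concatenate([h_f, h_b], axis=1)
        logits = feats @ params["wo"] + params["bo"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, feats, cache_f, cache_b

    def loss_and_grads(self, xs: np.ndarray, y: np.ndarray, params: dict):
        """Mean cross-entropy and exact gradients (used by the grad check)."""
        batch = xs.shape[1]
        probs, feats, cache_f, cache_b = self._forward(xs, params)
        loss = -np.mean(np.log(probs[np.arange(batch), y] + 1e-300))
        dlogits = probs.copy()
        dlogits[np.arange(batch), y] -= 1.0
        dlogits /= batch
        grads = {"wo": feats.T @ dlogits, "bo": dlogits.sum(axis=0)}
        dfeats = dlogits @ params["wo"].T
        g_f = _lstm_backward(dfeats[:, :self.n_hidden], cache_f,
                             self._split(params, "f_"))
        g_b = _lstm_backward(dfeats[:, self.n_hidden:], cache_b,
                             self._split(params, "b_"))
        grads.update({f"f_{k}": v for k, v in g_f.items()})
        grads.update({f"b_{k}": v for k, v in g_b.items()})
        return loss, grads

    # -- public API ------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray) -> "BiLSTMClassifier":
        x = np.asarray(x, float)
        y = np.asarray(y, int)
        if x.ndim != 3:
            raise ValueError("expected sequences of shape (n, T, d)")
        self._mu = x.mean(axis=(0, 1))
        self._sd = x.std(axis=(0, 1))
        self._sd[self._sd < 1e-12] = 1.0
        xs = ((x - self._mu) / self._sd).transpose(1, 0, 2)   # (T, B, d)
        params = self._init_params(x.shape[2])
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        for step in range(1, self.epochs + 1):
            _, grads = self.loss_and_grads(xs, y, params)
            for k in params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mhat = m[k] / (1 - b1 ** step)
                vhat = v[k] / (1 - b2 ** step)
                params[k] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
        self.params = params
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("classifier is not fitted")
        xs = ((np.asarray(x, float) - self._mu) / self._sd).transpose(1, 0, 2)
        probs, *_ = self._forward(xs, self.params)
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)
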