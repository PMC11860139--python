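"""A compact 1-D convolutional network in numpy for (200, 6) IMU windows.

Two conv→relu→maxpool blocks followed by a dense relu layer and a softmax
head, trained with Adam on categorical cross-entropy.  Written directly in
numpy: forward and backward passes use ``sliding_window_view`` + ``tensordot``
so a full training run (batch 40, 10 steps/epoch, 10 epochs) takes seconds on
one CPU, and every stage is deterministic under its seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (B, L, Cin), w: (k, Cin, Cout) -> (B, L-k+1, Cout), valid convolution
    windows = sliding_window_view(x, w.shape[0], axis=1)  # (B, Lout, Cin, k)
    return np.tensordot(windows, w, axes=([3, 2], [0, 1])) + b


def _conv1d_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray):
    k = w.shape[0]
    windows = sliding_window_view(x, k, axis=1)           # (B, Lout, Cin, k)
    dw = np.tensordot(windows, dy, axes=([0, 1], [0, 1])).transpose(1, 0, 2)
    db = dy.sum(axis=(0, 1))
    dy_pad = np.pad(dy, ((0, 0), (k - 1, k - 1), (0, 0)))
    dy_windows = sliding_window_view(dy_pad, k, axis=1)   # (B, L, Cout, k)
    dx = np.tensordot(dy_windows, w[::-1], axes=([3, 2], [0, 2]))
    return dx, dw, db


def _maxpool_forward(x: np.ndarray, size: int = 2):
    b, l, c = x.shape
    l2 = l // size
    blocks = x[:, : l2 * size].reshape(b, l2, size, c)
    arg = blocks.argmax(axis=2)
    return blocks.max(axis=2), arg


def _maxpool_backward(dy: np.ndarray, arg: np.ndarray, in_len: int, size: int = 2):
    b, l2, c = dy.shape
    dx = np.zeros((b, l2, size, c), dtype=dy.dtype)
    bi, li, ci = np.ogrid[:b, :l2, :c]
    dx[bi, li, arg, ci] = dy
    dx = dx.reshape(b, l2 * size, c)
    if dx.shape[1] < in_len:
        dx = np.pad(dx, ((0, 0), (0, in_len - dx.shape[1]), (0, 0)))
    return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TinyConvNet:
    """Multi-class 1-D convnet: conv(k,f1)→pool → conv(k,f2)→pool → dense → softmax."""

    def __init__(self, input_shape: tuple[int, int] = (200, 6), n_classes: int = 3,
                 filters: tuple[int, int] = (32, 64), kernel: int = 5,
                 dense: int = 64, seed: int = 0):
        self.input_shape = tuple(input_shape)
        self.n_classes = n_classes
        self.filters = tuple(filters)
        self.kernel = kernel
        self.dense = dense
        self.seed = seed
        rng = np.random.default_rng(seed)
        L, cin = input_shape
        f1, f2 = filters
        l1 = (L - kernel + 1) // 2
        l2 = (l1 - kernel + 1) // 2
        self.flat = l2 * f2

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "w1": he((kernel, cin, f1), kernel * cin), "b1": np.zeros(f1),
            "w2": he((kernel, f1, f2), kernel * f1), "b2": np.zeros(f2),
            "w3": he((self.flat, dense), self.flat), "b3": np.zeros(dense),
            "w4": he((dense, n_classes), dense), "b4": np.zeros(n_classes),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def _forward(self, x: np.ndarray):
        p = self.params
        z1 = _conv1d_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, arg1 = _maxpool_forward(a1)
        z2 = _conv1d_forward(p1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        p2, arg2 = _maxpool_forward(a2)
        flat = p2.reshape(len(x), -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        logits = a3 @ p["w4"] + p["b4"]
        probs = _softmax(logits)
        cache = (x, z1, a1, p1, arg1, z2, a2, p2, arg2, flat, z3, a3, probs)
        return probs, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValueError(f"expected (n, {self.input_shape[0]}, {self.input_shape[1]}) input, "
                             f"got {x.shape}")
        # chunked so inference memory stays flat for large batches
        return np.concatenate([self._forward(x[i:i + 256])[0]
                               for i in range(0, len(x), 256)])

    def _backward(self, cache, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        (x, z1, a1, p1, arg1, z2, a2, p2, arg2, flat, z3, a3, probs) = cache
        n = len(x)
        dlogits = (probs - y_onehot) / n
        grads = {"w4": a3.T @ dlogits, "b4": dlogits.sum(0)}
        da3 = dlogits @ p["w4"].T
        dz3 = da3 * (z3 > 0)
        grads["w3"] = flat.T @ dz3
        grads["b3"] = dz3.sum(0)
        dflat = dz3 @ p["w3"].T
        dp2 = dflat.reshape(p2.shape)
        da2 = _maxpool_backward(dp2, arg2, a2.shape[1])
        dz2 = da2 * (z2 > 0)
        dp1, grads["w2"], grads["b2"] = _conv1d_backward(p1, p["w2"], dz2)
        da1 = _maxpool_backward(dp1, arg1, a1.shape[1])
        dz1 = da1 * (z1 > 0)
        _, grads["w1"], grads["b1"] = _conv1d_backward(x, p["w1"], dz1)
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float,
                   beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            m_hat = self._adam_m[k] / (1 - beta1 ** t)
            v_hat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def fit(self, x: np.ndarray, y: np.ndarray, batch_size: int = 40,
            steps_per_epoch: int = 10, epochs: int = 10, lr: float = 1e-3,
            seed: int | None = None) -> list[float]:
        """Train on integer labels; returns the mean cross-entropy per epoch.

        Each epoch shuffles the data and draws ``steps_per_epoch`` batches of
        ``batch_size`` (cycling when the pool is smaller).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        onehot = np.eye(self.n_classes)[y]
        history: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(len(x))
            need = batch_size * steps_per_epoch
            if len(order) < need:
                order = np.tile(order, int(np.ceil(need / len(order))))
            losses = []
            for s in range(steps_per_epoch):
                idx = order[s * batch_size:(s + 1) * batch_size]
                probs, cache = self._forward(x[idx])
                loss = -np.mean(np.sum(onehot[idx] * np.log(probs + 1e-12), axis=1))
                losses.append(float(loss))
                self._adam_step(self._backward(cache, onehot[idx]), lr)
            history.append(float(np.mean(losses)))
        return history

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(weights[k], dtype=float).copy()
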