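"""Minimal feed-forward layer stack with manual backpropagation.

Implements exactly what the two classifier architectures need — 1-D valid
convolution, non-overlapping max pooling, dense layers, ReLU/sigmoid and
a softmax cross-entropy head — trained by plain mini-batch SGD. All
arithmetic is float32; gradients are averaged over the mini-batch by the
loss head.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class Layer:
    """Base layer: parameter-free unless ``params`` is non-empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.velocity: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv1D(Layer):
    """Valid (no padding), stride-1 one-dimensional convolution.

    Input ``(B, C, L)`` (a plain ``(B, L)`` matrix is treated as one
    channel), output ``(B, F, L - kernel_size + 1)``.
    """

    def __init__(self, in_channels: int, n_kernels: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init, ReLU downstream
        self.params["W"] = (rng.standard_normal((n_kernels, in_channels, kernel_size)) * scale).astype(DTYPE)
        self.params["b"] = np.zeros(n_kernels, dtype=DTYPE)
        self._squeeze_input = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._squeeze_input = x.ndim == 2
        if self._squeeze_input:
            x = x[:, None, :]
        self._windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel_size, axis=2)
        self._in_len = x.shape[2]
        return np.einsum("bctu,fcu->bft", self._windows, self.params["W"],
                         optimize=True) + self.params["b"][None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        self.grads["W"] = np.einsum("bft,bctu->fcu", dout, self._windows, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2))
        B, _, T = dout.shape
        dx = np.zeros((B, self.in_channels, self._in_len), dtype=DTYPE)
        for u in range(self.kernel_size):
            dx[:, :, u:u + T] += np.einsum("bft,fc->bct", dout, W[:, :, u], optimize=True)
        return dx[:, 0, :] if self._squeeze_input else dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder window is dropped."""

    def __init__(self, size: int) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        T = L // self.size
        self._in_shape = x.shape
        xt = x[:, :, : T * self.size].reshape(B, C, T, self.size)
        self._argmax = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, T = dout.shape
        dxt = np.zeros((B, C, T, self.size), dtype=DTYPE)
        np.put_along_axis(dxt, self._argmax[..., None], dout[..., None], axis=3)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        dx[:, :, : T * self.size] = dxt.reshape(B, C, T * self.size)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = sigmoid(x)
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 W: np.ndarray | None = None, b: np.ndarray | None = None) -> None:
        super().__init__()
        if W is None:
            scale = np.sqrt(2.0 / n_in)
            W = (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE)
        if b is None:
            b = np.zeros(n_out, dtype=DTYPE)
        self.params["W"] = W
        self.params["b"] = b

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(p[np.arange(B), y], 1e-300)).mean()
    dlogits = p
    dlogits[np.arange(B), y] -= 1.0
    return float(loss), (dlogits / B).astype(DTYPE)


class Network:
    """A sequential stack of layers ending in class logits."""

    def __init__(self, layers: list[Layer], input_len: int, n_classes: int) -> None:
        self.layers = layers
        self.input_len = input_len
        self.n_classes = n_classes

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def sgd_step(self, lr: float, momentum: float = 0.0) -> None:
        for layer in self.layers:
            for name, g in layer.grads.items():
                if momentum > 0.0:
                    v = layer.velocity.setdefault(name, np.zeros_like(layer.params[name]))
                    v *= DTYPE(momentum)
                    v -= DTYPE(lr) * g.astype(DTYPE)
                    layer.params[name] += v
                else:
                    layer.params[name] -= lr * g.astype(DTYPE)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        if X.shape[1] != self.input_len:
            raise ValueError(
                f"input has {X.shape[1]} features but the model expects {self.input_len}"
            )
        out = np.empty((X.shape[0], self.n_classes), dtype=np.float64)
        for i in range(0, X.shape[0], batch_size):
            out[i:i + batch_size] = softmax(
                self.forward(X[i:i + batch_size].astype(DTYPE)).astype(np.float64)
            )
        return out

    def n_parameters(self) -> int:
        return sum(layer.n_parameters() for layer in self.layers)
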