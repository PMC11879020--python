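"""Feed-forward building blocks: dense, conv, pooling, normalisation."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: parameter dict, gradient dict, cached forward state."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    """Affine map over the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": glorot(rng, n_in, n_out, (n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.zero_grads()

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += x2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Conv1D(Layer):
    """Valid-padding 1D convolution on (batch, channels, length) input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.params = {
            "W": glorot(rng, c_in * kernel, c_out, (c_out, c_in, kernel)),
            "b": np.zeros(c_out),
        }
        self.zero_grads()

    def out_length(self, length: int) -> int:
        return length - self.kernel + 1

    def forward(self, x, training=False):
        k = self.kernel
        if x.shape[2] < k:
            raise ValueError(f"input length {x.shape[2]} shorter than kernel {k}")
        # patches: (B, C, L_out, k) -> (B, L_out, C*k)
        patches = sliding_window_view(x, k, axis=2)
        B, C, Lo, _ = patches.shape
        self._patches = patches.transpose(0, 2, 1, 3).reshape(B, Lo, C * k)
        self._in_shape = x.shape
        Wm = self.params["W"].reshape(self.params["W"].shape[0], -1)  # (F, C*k)
        y = self._patches @ Wm.T + self.params["b"]  # (B, Lo, F)
        return y.transpose(0, 2, 1)

    def backward(self, dy):
        # dy: (B, F, Lo)
        k = self.kernel
        B, C, L = self._in_shape
        F = dy.shape[1]
        dyt = dy.transpose(0, 2, 1)  # (B, Lo, F)
        Lo = dyt.shape[1]
        dW = dyt.reshape(-1, F).T @ self._patches.reshape(-1, C * k)
        self.grads["W"] += dW.reshape(self.params["W"].shape)
        self.grads["b"] += dyt.sum(axis=(0, 1))
        Wm = self.params["W"].reshape(F, -1)
        dpatches = (dyt @ Wm).reshape(B, Lo, C, k)
        dx = np.zeros((B, C, L))
        for i in range(k):
            dx[:, :, i : i + Lo] += dpatches[:, :, :, i].transpose(0, 2, 1)
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (floor division)."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def out_length(self, length: int) -> int:
        return length // self.pool

    def forward(self, x, training=False):
        p = self.pool
        B, C, L = x.shape
        Lo = L // p
        if Lo < 1:
            raise ValueError(f"pool {p} reduces length {L} below 1")
        self._in_shape = x.shape
        xv = x[:, :, : Lo * p].reshape(B, C, Lo, p)
        self._argmax = xv.argmax(axis=3)
        return xv.max(axis=3)

    def backward(self, dy):
        p = self.pool
        B, C, L = self._in_shape
        Lo = dy.shape[2]
        dxv = np.zeros((B, C, Lo, p))
        np.put_along_axis(dxv, self._argmax[..., None], dy[..., None], axis=3)
        dx = np.zeros((B, C, L))
        dx[:, :, : Lo * p] = dxv.reshape(B, C, Lo * p)
        return dx


class BatchNorm1D(Layer):
    """Per-channel batch normalisation on (batch, channels, length) input."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grads()

    def forward(self, x, training=False):
        self._training = training
        g = self.params["gamma"][None, :, None]
        b = self.params["beta"][None, :, None]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)[None, :, None]
            self._xhat = (x - mean[None, :, None]) / self._std
            return g * self._xhat + b
        std = np.sqrt(self.running_var + self.eps)[None, :, None]
        self._eval_std = std
        self._xhat = (x - self.running_mean[None, :, None]) / std
        return g * self._xhat + b

    def backward(self, dy):
        g = self.params["gamma"][None, :, None]
        self.grads["gamma"] += (dy * self._xhat).sum(axis=(0, 2))
        self.grads["beta"] += dy.sum(axis=(0, 2))
        if not self._training:
            return dy * g / self._eval_std
        N = dy.shape[0] * dy.shape[2]
        dxhat = dy * g
        m1 = dxhat.mean(axis=(0, 2))[None, :, None]
        m2 = (dxhat * self._xhat).mean(axis=(0, 2))[None, :, None]
        return (dxhat - m1 - self._xhat * m2) / self._std

    def state_dict(self):
        state = super().state_dict()
        state["running_mean"] = self.running_mean.copy()
        state["running_var"] = self.running_var.copy()
        return state

    def load_state_dict(self, state):
        super().load_state_dict(state)
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()


class LayerNorm(Layer):
    """Normalisation over the last axis (token features)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.zero_grads()

    def forward(self, x, training=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat = self._xhat
        self.grads["gamma"] += (dy * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.grads["beta"] += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        dxhat = dy * self.params["gamma"]
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return (dxhat - m1 - xhat * m2) / self._std


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time.

    The RNG is injected by the training loop (see ``train.train_model``) so
    seeded runs are reproducible.
    """

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Sequential:
    """A straight chain of layers with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def state_dict(self):
        return {i: layer.state_dict() for i, layer in enumerate(self.layers)}

    def load_state_dict(self, state):
        for i, layer in enumerate(self.layers):
            layer.load_state_dict(state[i])

    def dropout_layers(self):
        return [l for l in self.layers if isinstance(l, Dropout)]
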