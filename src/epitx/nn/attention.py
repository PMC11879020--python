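"""Masked multi-head self-attention and a pre-pooling transformer block."""

from __future__ import annotations

import numpy as np

from epitx.nn.layers import Layer, Dense, ReLU, LayerNorm


class MultiHeadSelfAttention(Layer):
    """Standard scaled dot-product self-attention with a key padding mask.

    Input (B, T, D), mask (B, T) with True = valid token.  Padded tokens are
    excluded as *keys* (so no information flows out of them); their output
    rows are computed but are discarded by the masked pooling downstream.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"embed dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.dk = dim // heads
        self.proj = {
            name: Dense(dim, dim, rng) for name in ("q", "k", "v", "o")
        }

    # parameter plumbing delegates to the four projections
    @property
    def params(self):  # type: ignore[override]
        return {
            f"{n}_{k}": v for n, p in self.proj.items() for k, v in p.params.items()
        }

    @params.setter
    def params(self, value):
        if value:
            raise AttributeError("set projection params directly")

    def zero_grads(self):
        for p in self.proj.values():
            p.zero_grads()

    def state_dict(self):
        return {n: p.state_dict() for n, p in self.proj.items()}

    def load_state_dict(self, state):
        for n, p in self.proj.items():
            p.load_state_dict(state[n])

    def sublayers(self):
        return list(self.proj.values())

    def _split(self, x):
        B, T, _ = x.shape
        return x.reshape(B, T, self.heads, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x):
        B, h, T, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)

    def forward(self, x, mask=None, training=False):
        B, T, D = x.shape
        q = self._split(self.proj["q"].forward(x, training))
        k = self._split(self.proj["k"].forward(x, training))
        v = self._split(self.proj["v"].forward(x, training))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dk)  # (B,h,T,T)
        if mask is not None:
            scores = np.where(mask[:, None, None, :], scores, -1e30)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        att = e / e.sum(axis=-1, keepdims=True)
        self._att, self._q, self._k, self._v = att, q, k, v
        out = self._merge(att @ v)
        return self.proj["o"].forward(out, training)

    def backward(self, dy):
        att, q, k, v = self._att, self._q, self._k, self._v
        dout = self._split(self.proj["o"].backward(dy))
        datt = dout @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ dout
        ds = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        ds /= np.sqrt(self.dk)
        dq = ds @ k
        dk_ = ds.transpose(0, 1, 3, 2) @ q
        dx = self.proj["q"].backward(self._merge(dq))
        dx += self.proj["k"].backward(self._merge(dk_))
        dx += self.proj["v"].backward(self._merge(dv))
        return dx


class TransformerBlock:
    """Attention + position-wise feed-forward, both with residuals and LayerNorm."""

    def __init__(self, dim: int, heads: int, ff_dim: int, rng: np.random.Generator):
        self.att = MultiHeadSelfAttention(dim, heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ff1 = Dense(dim, ff_dim, rng)
        self.relu = ReLU()
        self.ff2 = Dense(ff_dim, dim, rng)
        self.ln2 = LayerNorm(dim)

    def sublayers(self):
        return self.att.sublayers() + [self.ln1, self.ff1, self.ff2, self.ln2]

    def forward(self, x, mask=None, training=False):
        a = self.att.forward(x, mask=mask, training=training)
        h = self.ln1.forward(x + a, training)
        f = self.ff2.forward(
            self.relu.forward(self.ff1.forward(h, training), training), training
        )
        return self.ln2.forward(h + f, training)

    def backward(self, dy):
        d = self.ln2.backward(dy)
        dh = d + self.ff1.backward(self.relu.backward(self.ff2.backward(d)))
        d1 = self.ln1.backward(dh)
        return d1 + self.att.backward(d1)

    def zero_grads(self):
        for l in self.sublayers():
            l.zero_grads()

    def state_dict(self):
        return {
            "att": self.att.state_dict(),
            "ln1": self.ln1.state_dict(),
            "ff1": self.ff1.state_dict(),
            "ff2": self.ff2.state_dict(),
            "ln2": self.ln2.state_dict(),
        }

    def load_state_dict(self, state):
        self.att.load_state_dict(state["att"])
        self.ln1.load_state_dict(state["ln1"])
        self.ff1.load_state_dict(state["ff1"])
        self.ff2.load_state_dict(state["ff2"])
        self.ln2.load_state_dict(state["ln2"])
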