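"""Adam optimiser over leaf layers' parameter dicts."""

from __future__ import annotations

import numpy as np


class Adam:
    """ADAM with the usual defaults; learning rate is set per step.

    ``layers`` is the flat list of leaf layers (each with real ``params``
    and ``grads`` dicts).  Gradients are zeroed after every step.
    """

    def __init__(self, layers, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in layers
        ]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= lr * (m[k] / c1) / (np.sqrt(v[k] / c2) + self.eps)
            l.zero_grads()
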