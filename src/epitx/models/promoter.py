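"""Convolutional regression over the 60-bin promoter window.

Architecture: three convolutional blocks (conv -> batch norm -> ReLU ->
max-pool -> dropout), then two fully connected blocks (dropout in the
first), then a linear output neuron predicting log2(RPKM+1).  Marks enter
as input channels over the 60 bins.  Exact layer sizes are configuration,
not doctrine; defaults are DeepChrome-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from epitx.nn import (
    Sequential,
    Conv1D,
    BatchNorm1D,
    ReLU,
    MaxPool1D,
    Dropout,
    Flatten,
    Dense,
)


@dataclass
class PromoterModelConfig:
    n_marks: int = 1
    n_bins: int = 60
    # (filters, kernel, pool, dropout) per convolutional block
    conv_blocks: tuple = ((50, 10, 2, 0.1), (50, 5, 2, 0.1), (50, 5, 2, 0.1))
    fc_sizes: tuple = (128, 32)
    fc_dropout: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_marks < 1:
            raise ValueError("n_marks must be >= 1")
        if not self.conv_blocks:
            raise ValueError("need at least one convolutional block")
        length = self.n_bins
        for i, (filters, kernel, pool, _) in enumerate(self.conv_blocks):
            length = length - kernel + 1
            if length < 1:
                raise ValueError(f"conv block {i}: kernel {kernel} exceeds length")
            length //= pool
            if length < 1:
                raise ValueError(f"conv block {i}: pooling {pool} reduces length below 1")


class PromoterModel:
    """(n_marks x 60) -> scalar expression, with input-gradient support."""

    def __init__(self, config: PromoterModelConfig, mark_names: tuple[str, ...] = ("mark",)):
        config.validate()
        self.config = config
        self.mark_names = tuple(mark_names)
        rng = np.random.default_rng(config.seed)
        layers = []
        c_in, length = config.n_marks, config.n_bins
        for filters, kernel, pool, drop in config.conv_blocks:
            layers += [
                Conv1D(c_in, filters, kernel, rng),
                BatchNorm1D(filters),
                ReLU(),
                MaxPool1D(pool),
                Dropout(drop),
            ]
            length = (length - kernel + 1) // pool
            c_in = filters
        layers.append(Flatten())
        n_in = c_in * length
        for i, size in enumerate(config.fc_sizes):
            if i == 0:
                layers.append(Dropout(config.fc_dropout))
            layers += [Dense(n_in, size, rng), ReLU()]
            n_in = size
        layers.append(Dense(n_in, 1, rng))
        self.net = Sequential(layers)

    # --- training engine contract -----------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(x, training=training)[:, 0]

    def backward(self, dpred: np.ndarray) -> np.ndarray:
        return self.net.backward(dpred[:, None])

    def param_layers(self):
        return [l for l in self.net.layers if l.params]

    def dropout_layers(self):
        return self.net.dropout_layers()

    def state_dict(self):
        return self.net.state_dict()

    def load_state_dict(self, state):
        self.net.load_state_dict(state)

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out) if out else np.empty(0)

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(prediction)/d(input bin) per example, in evaluation mode."""
        self.forward(x, training=False)
        return self.backward(np.ones(len(x)))


def build_promoter_model(
    config: PromoterModelConfig, mark_names: tuple[str, ...] = ("mark",)
) -> PromoterModel:
    return PromoterModel(config, mark_names)
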