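"""Shared training engine: MSE + ADAM, plateau LR decay, early stopping.

Both the promoter and distal models train through this loop.  "Improvement"
means the validation loss decreases by more than ``min_delta``; the learning
rate is multiplied by ``lr_decay_factor`` after ``lr_patience`` consecutive
epochs without improvement (counter resets after each decay), and training
stops after ``early_stop_patience`` epochs without improvement or at
``max_epochs``, restoring the best-validation-loss weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epitx.models.data import n_examples, take_batch
from epitx.nn import Adam


@dataclass
class TrainingSchedule:
    batch_size: int = 64
    max_epochs: int = 100
    early_stop_patience: int = 12
    lr_init: float = 0.001
    lr_decay_factor: float = 0.2
    lr_patience: int = 3
    min_delta: float = 1e-6

    def validate(self) -> None:
        if self.early_stop_patience < 1 or self.lr_patience < 1:
            raise ValueError("patiences must be >= 1")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr decay factor must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class ScheduleState:
    """Pure plateau/early-stop bookkeeping, one `update` per epoch."""

    schedule: TrainingSchedule
    lr: float = field(init=False)
    best_loss: float = field(init=False, default=np.inf)
    best_epoch: int = field(init=False, default=0)
    epoch: int = field(init=False, default=0)
    _since_best: int = field(init=False, default=0)
    _since_decay: int = field(init=False, default=0)

    def __post_init__(self):
        self.schedule.validate()
        self.lr = self.schedule.lr_init

    def update(self, val_loss: float) -> tuple[bool, bool]:
        """Record one epoch's validation loss; returns (decayed, stop)."""
        self.epoch += 1
        if val_loss < self.best_loss - self.schedule.min_delta:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
            self._since_best = 0
            self._since_decay = 0
            return False, False
        self._since_best += 1
        self._since_decay += 1
        decayed = False
        if self._since_decay >= self.schedule.lr_patience:
            self.lr *= self.schedule.lr_decay_factor
            self._since_decay = 0
            decayed = True
        stop = self._since_best >= self.schedule.early_stop_patience
        return decayed, stop


@dataclass
class TrainedModel:
    model: object
    history: pd.DataFrame
    best_epoch: int
    fold: int | None = None
    mark_names: tuple = ()
    cell: str | None = None

    def predict(self, inputs):
        return self.model.predict(inputs)

    def input_gradient(self, inputs):
        return self.model.input_gradient(inputs)

    @property
    def config(self):
        return self.model.config


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2))


def train_model(
    model,
    train: tuple,
    val: tuple,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
    fold: int | None = None,
    cell: str | None = None,
) -> TrainedModel:
    """Fit ``model`` on (inputs, targets) pairs with the shared schedule."""
    schedule = schedule or TrainingSchedule()
    schedule.validate()
    train_x, train_y = train
    val_x, val_y = val
    n_train = n_examples(train_x)
    if n_train == 0 or n_examples(val_x) == 0:
        raise ValueError("train and validation sets must be non-empty")
    train_y = np.asarray(train_y, dtype=float)
    val_y = np.asarray(val_y, dtype=float)

    rng = np.random.default_rng(seed)
    for d in model.dropout_layers():
        d.rng = np.random.default_rng(rng.integers(2**31))

    opt = Adam(model.param_layers())
    state = ScheduleState(schedule)
    best_weights = model.state_dict()
    history = []
    for epoch in range(1, schedule.max_epochs + 1):
        order = rng.permutation(n_train)
        losses = []
        for i in range(0, n_train, schedule.batch_size):
            idx = order[i : i + schedule.batch_size]
            xb = take_batch(train_x, idx)
            yb = train_y[idx]
            pred = model.forward(xb, training=True)
            losses.append(_mse(pred, yb))
            model.backward(2.0 * (pred - yb) / len(yb))
            opt.step(state.lr)
        val_loss = _mse(model.predict(val_x), val_y)
        history.append(
            dict(epoch=epoch, train_loss=float(np.mean(losses)), val_loss=val_loss, lr=state.lr)
        )
        improved = val_loss < state.best_loss - schedule.min_delta
        _, stop = state.update(val_loss)
        if improved:
            best_weights = model.state_dict()
        if stop:
            break
    model.load_state_dict(best_weights)
    return TrainedModel(
        model=model,
        history=pd.DataFrame(history),
        best_epoch=state.best_epoch,
        fold=fold,
        mark_names=getattr(model, "mark_names", ()),
        cell=cell,
    )


def pearson_r(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson correlation; ``None`` if either side has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return None
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


@dataclass
class ScoreResult:
    predictions: np.ndarray
    pearson_r: float | None


def predict_and_score(model, inputs, targets) -> ScoreResult:
    preds = model.predict(inputs)
    return ScoreResult(predictions=preds, pearson_r=pearson_r(preds, np.asarray(targets)))
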