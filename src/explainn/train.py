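"""Model training: losses, optimization, early stopping, augmentation.

Training uses Adam (learning rate 0.003, batch size 100 by default) with a
task-appropriate loss: binary cross-entropy on post-sigmoid outputs for
binary multi-task labels, softmax cross-entropy for multiclass, and mean
squared error for regression. The model's final layer stays linear; the
sigmoid/softmax lives in the loss.

Training and validation sets are augmented with the reverse complement of
every sequence (identical labels) unless disabled. Early stopping monitors
validation loss; the returned model is the one from the best validation
epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import LabeledDataset
from .model import ExplaiNNModel
from ._nn import Adam

LOSS_FOR_TASK = {
    "binary_multitask": "bce",
    "multiclass": "cross_entropy",
    "regression": "mse",
}


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 0.003
    batch_size: int = 100
    loss: str | None = None  # default: inferred from the task type
    optimizer: str = "adam"
    patience: int = 10
    max_epochs: int = 100
    rc_augment: bool = True
    seed: int = 0

    def validate(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss is not None and self.loss not in ("bce", "mse", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


# --------------------------------------------------------------------------
# losses (value and gradient w.r.t. the linear model outputs)
# --------------------------------------------------------------------------

def sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(logits, labels):
    """Mean binary cross-entropy of sigmoid(logits) against 0/1 labels."""
    z, y = np.asarray(logits, float), np.asarray(labels, float)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return loss.mean(), grad


def mse_loss(pred, labels):
    p, y = np.asarray(pred, float), np.asarray(labels, float)
    diff = p - y
    return (diff ** 2).mean(), 2.0 * diff / p.size


def cross_entropy_loss(logits, labels):
    """Softmax cross-entropy; labels are one-hot rows."""
    z, y = np.asarray(logits, float), np.asarray(labels, float)
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -(y * logp).sum(axis=1).mean()
    grad = (np.exp(logp) - y) / z.shape[0]
    return loss, grad


LOSSES = {"bce": bce_loss, "mse": mse_loss, "cross_entropy": cross_entropy_loss}


def resolve_loss(task_type: str, requested: str | None) -> str:
    expected = LOSS_FOR_TASK[task_type]
    if requested is None:
        return expected
    if requested != expected:
        raise ValueError(
            f"loss {requested!r} is incompatible with task type "
            f"{task_type!r} (expected {expected!r})"
        )
    return requested


# --------------------------------------------------------------------------
# early stopping
# --------------------------------------------------------------------------

class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch; returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

def _eval_loss(model, x, y, loss_fn, batch_size=1000):
    total, n = 0.0, x.shape[0]
    for start in range(0, n, batch_size):
        xb = x[start:start + batch_size]
        pred, _ = model.forward(xb, training=False)
        loss, _ = loss_fn(pred, y[start:start + batch_size])
        total += loss * xb.shape[0]
    return total / n


def train(model: ExplaiNNModel, train_set: LabeledDataset,
          val_set: LabeledDataset, config: TrainConfig | None = None):
    """Train in place and return ``(best_model, history)``.

    ``history`` is a DataFrame with per-epoch train/val loss. The returned
    model carries the parameters of the best validation epoch. Runs are
    deterministic given ``config.seed`` (single-threaded).
    """
    config = config if config is not None else TrainConfig()
    config.validate()
    if train_set.task_type != val_set.task_type:
        raise ValueError("train and validation sets have different task types")
    loss_name = resolve_loss(train_set.task_type, config.loss)
    loss_fn = LOSSES[loss_name]

    if config.rc_augment:
        train_set = train_set.with_reverse_complements()
        val_set = val_set.with_reverse_complements()
    x_train = train_set.encode()
    x_val = val_set.encode()
    if x_train.shape[1] != model.config.input_length:
        raise ValueError(
            f"dataset length {x_train.shape[1]} does not match model input "
            f"length {model.config.input_length}"
        )
    y_train, y_val = train_set.labels, val_set.labels
    if y_train.shape[1] != model.config.num_tasks:
        raise ValueError(
            f"dataset has {y_train.shape[1]} tasks, model expects "
            f"{model.config.num_tasks}"
        )

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(lr=config.learning_rate)
    stopper = EarlyStopper(config.patience)
    history = []
    best_state = None
    n = x_train.shape[0]

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size < 2:
                continue  # batch norm needs at least two samples
            pred, _ = model.forward(x_train[idx], training=True, rng=rng)
            loss, dpred = loss_fn(pred, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}; reduce the "
                    "learning rate or inspect the labels"
                )
            grads = model.backward(dpred)
            optimizer.step(model.trainable_parameters(), grads)
            epoch_loss += loss * idx.size
            seen += idx.size
        val_loss = _eval_loss(model, x_val, y_val, loss_fn)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history.append({"epoch": epoch, "train_loss": epoch_loss / max(seen, 1),
                        "val_loss": val_loss})
        if val_loss < stopper.best:
            best_state = _snapshot(model)
        if stopper.update(epoch, val_loss):
            break

    if best_state is not None:
        _restore(model, best_state)
    return model, pd.DataFrame(history)


def _snapshot(model: ExplaiNNModel):
    return (
        {k: v.copy() for k, v in model.params.items()},
        {name: st.copy() for name, st in model.bn_states().items()},
    )


def _restore(model: ExplaiNNModel, state) -> None:
    params, bns = state
    for k, v in params.items():
        model.params[k][...] = v
    for name, st in model.bn_states().items():
        saved = bns[name]
        st.gamma[...] = saved.gamma
        st.beta[...] = saved.beta
        st.running_mean[...] = saved.running_mean
        st.running_var[...] = saved.running_var


# --------------------------------------------------------------------------
# signal preprocessing
# --------------------------------------------------------------------------

def quantile_normalize(values) -> np.ndarray:
    """Map values to uniform quantiles by rank (ties get the average rank).

    Output for rank r among n values is (r - 0.5) / n, a monotone,
    rank-preserving transform onto (0, 1). An all-identical input maps to
    the median target quantile 0.5 everywhere.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("quantile_normalize requires finite values")
    ranks = rankdata(v, method="average")
    return (ranks - 0.5) / v.size
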