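"""Training loop: cross-entropy, Adam with decoupled weight decay, and a
reduce-on-plateau learning-rate schedule.

The protocol: 30 epochs, batch size 256, Adam at an initial learning rate
of 0.001 with weight-decay factor 0.0005; one tenth of the training set
is held out (stratified by label) as a validation set; when the monitored
validation loss fails to improve for ``lr_patience`` consecutive epochs
the learning rate is multiplied by ``lr_factor`` (0.1), floored at 1e-6.
The checkpoint with the best validation accuracy is restored at the end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from emgfuse import nn
from emgfuse.preprocess import PairedWindows, WindowSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; defaults follow the training-hyperparameter table."""

    epochs: int = 30
    batch_size: int = 256
    initial_lr: float = 0.001
    weight_decay: float = 0.0005
    lr_factor: float = 0.1
    lr_patience: int = 1
    min_lr: float = 1e-6
    dropout: float = 0.5
    val_fraction: float = 0.1
    seed: int = 0
    monitor: str = "val_loss"  # or "val_accuracy"
    # one optimizer step still covers batch_size windows; gradients are
    # accumulated over micro-batches of this size to bound im2col memory
    micro_batch: int = 32

    def __post_init__(self) -> None:
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must be in (0, 1)")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch metrics; ``best_epoch`` indexes the restored checkpoint."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_accuracy": self.train_accuracy,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
                "learning_rate": self.learning_rate,
            }
        )


def cross_entropy_loss(y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1e-12) -> float:
    """Mean over samples of -sum_i y_i log(max(yhat_i, eps)).

    ``y_true`` is one-hot (n, n_classes); ``y_pred`` rows are probability
    vectors.  The eps floor keeps the loss finite on saturated predictions.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if not np.allclose(y_pred.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("y_pred rows must sum to 1")
    return float(-(y_true * np.log(np.maximum(y_pred, eps))).sum(axis=1).mean() + 0.0)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def split_validation(
    windows: PairedWindows, val_fraction: float, seed: int
) -> tuple[PairedWindows, PairedWindows]:
    """Stratified-by-label random split preserving EMG/ACC pairing.

    Falls back to an unstratified split (with a warning) when any class
    has fewer than 2 windows.
    """
    if not 0 <= val_fraction < 1:
        raise ValueError("val_fraction must be in [0, 1)")
    n = windows.n_windows
    idx = np.arange(n)
    if val_fraction == 0 or round(n * val_fraction) == 0:
        return windows, windows.subset(idx[:0])
    labels = windows.labels
    _, counts = np.unique(labels, return_counts=True)
    stratify = labels
    if counts.min() < 2:
        warnings.warn(
            "a class has fewer than 2 windows; falling back to an "
            "unstratified validation split",
            stacklevel=2,
        )
        stratify = None
    tr_idx, va_idx = train_test_split(
        idx, test_size=val_fraction, random_state=seed % (2**31), stratify=stratify
    )
    return windows.subset(np.sort(tr_idx)), windows.subset(np.sort(va_idx))


def _model_inputs(model, part: PairedWindows, y: np.ndarray):
    """(inputs tuple, labels) for either a two-stream or single-stream model."""
    from emgfuse.model import SingleStream, TwoStream

    if isinstance(model, TwoStream):
        return (part.emg.x, part.acc.x), y
    if isinstance(model, SingleStream):
        kind = "emg" if model.branch.spec.input_shape[0] == part.emg.x.shape[1] else "acc"
        ws: WindowSet = getattr(part, kind)
        return (ws.x,), y
    raise TypeError(f"unsupported model type {type(model)!r}")


def _evaluate_split(model, inputs, y_idx, chunk_size: int) -> tuple[float, float]:
    loss_fn = model.loss_fn
    losses, correct, total = [], 0, 0
    n = inputs[0].shape[0]
    for i in range(0, n, chunk_size):
        chunk = tuple(a[i : i + chunk_size] for a in inputs)
        logits = model.forward_logits(*chunk, train=False)
        loss, p = loss_fn.forward(logits, y_idx[i : i + chunk_size])
        losses.append(loss * chunk[0].shape[0])
        correct += int((p.argmax(axis=1) == y_idx[i : i + chunk_size]).sum())
        total += chunk[0].shape[0]
    return sum(losses) / total, correct / total


def train_model(model, data: PairedWindows, config: TrainConfig):
    """Train a (two- or single-stream) model on paired windows.

    Labels may be arbitrary gesture ids; they are mapped to 0..K-1 through
    the sorted unique labels of ``data`` (stored on the model as
    ``model.classes_``).  Returns ``(model, TrainHistory)`` with the
    best-validation-accuracy checkpoint restored (final state when no
    validation set is held out).

    Raises ``FloatingPointError`` if the loss becomes non-finite.
    """
    if data.n_windows == 0:
        raise ValueError("training data is empty")
    classes = np.unique(data.labels)
    if classes.size < 2:
        raise ValueError("training data must cover at least 2 classes")
    model.classes_ = classes

    train_part, val_part = split_validation(data, config.val_fraction, config.seed)
    lut = {c: i for i, c in enumerate(classes)}
    y_tr = np.array([lut[c] for c in train_part.labels])
    y_va = np.array([lut[c] for c in val_part.labels])
    tr_inputs, y_tr = _model_inputs(model, train_part, y_tr)
    va_inputs, y_va = _model_inputs(model, val_part, y_va)
    have_val = y_va.shape[0] > 0

    opt = nn.AdamW(model, lr=config.initial_lr, weight_decay=config.weight_decay)
    sched = nn.ReduceLROnPlateau(
        opt, factor=config.lr_factor, patience=config.lr_patience, min_lr=config.min_lr
    )
    rng = np.random.default_rng([config.seed % (2**31), 0x7124])
    history = TrainHistory()
    best_acc, best_loss, best_state = -1.0, np.inf, None
    n = y_tr.shape[0]

    mb = max(1, min(config.micro_batch, config.batch_size))
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            sel = order[i : i + config.batch_size]
            model.zero_grads()
            for j in range(0, sel.size, mb):
                sub = sel[j : j + mb]
                batch = tuple(a[sub] for a in tr_inputs)
                yb = y_tr[sub]
                logits = model.forward_logits(*batch, train=True)
                loss, p = model.loss_fn.forward(logits, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged: non-finite loss at epoch {epoch + 1}"
                    )
                # scale so accumulated grads average over the full batch
                model.backward_from_logits(
                    model.loss_fn.backward() * (sub.size / sel.size)
                )
                ep_loss += loss * sub.size
                ep_correct += int((p.argmax(axis=1) == yb).sum())
            opt.step()
        history.train_loss.append(ep_loss / n)
        history.train_accuracy.append(ep_correct / n)
        history.learning_rate.append(opt.lr)

        if have_val:
            v_loss, v_acc = _evaluate_split(model, va_inputs, y_va, mb)
        else:
            v_loss, v_acc = history.train_loss[-1], history.train_accuracy[-1]
        history.val_loss.append(v_loss)
        history.val_accuracy.append(v_acc)
        logger.info(
            "epoch %d/%d: train_loss=%.4f train_acc=%.4f val_loss=%.4f "
            "val_acc=%.4f lr=%.2e",
            epoch + 1, config.epochs, history.train_loss[-1],
            history.train_accuracy[-1], v_loss, v_acc, opt.lr,
        )
        # best validation accuracy; ties resolved toward lower validation loss
        if v_acc > best_acc or (v_acc == best_acc and v_loss < best_loss):
            best_acc, best_loss = v_acc, v_loss
            best_state = model.state_dict()
            history.best_epoch = epoch + 1
        sched.step(v_loss if config.monitor == "val_loss" else -v_acc)

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def save_checkpoint(model, path: str) -> None:
    """Serialize all parameters and batch-norm buffers to one .npz file."""
    state = model.state_dict()
    if hasattr(model, "classes_"):
        state["__classes__"] = np.asarray(model.classes_)
    np.savez(path, **state)


def load_checkpoint(model, path: str):
    """Restore a checkpoint written by :func:`save_checkpoint` in place."""
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    if "__classes__" in state:
        model.classes_ = state.pop("__classes__")
    model.load_state_dict(state)
    return model
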