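"""Training protocol: weighted cross-entropy, Adam, recall-plateau
learning-rate decay, best-validation-recall checkpointing.

The canonical settings are 50 epochs, batch size 8, initial learning
rate 1e-4 decayed by a factor 0.8 whenever validation macro recall has
not strictly improved for 3 consecutive epochs, and the returned model
is the checkpoint with the best validation macro recall.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import recall_score

from cytomil.data import Bag
from cytomil.models.admil import ADMIL
from cytomil.models.tcs_cnn import TCSCNN
from cytomil.nn.functional import softmax
from cytomil.nn.optim import Adam

EPS = 1e-7  # probability clip before the log


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    initial_lr: float = 1e-4
    lr_factor: float = 0.8
    lr_patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.lr_patience < 1:
            raise ValueError("lr_patience must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_recall: list[float] = field(default_factory=list)
    val_recall: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1


def wce_loss(y: np.ndarray, p_hat: np.ndarray, w: np.ndarray) -> float:
    """Weighted cross-entropy, the exact double sum
    -sum_i sum_j w_j y_ij log(p_ij) over one-hot labels y (M, C) and
    predicted probabilities p_hat (M, C); probabilities are clipped to
    [EPS, 1] before the log."""
    y = np.asarray(y, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.shape != p_hat.shape or y.shape[1] != w.size:
        raise ValueError("shape mismatch between labels, probabilities and weights")
    return float(-(y * w[None, :] * np.log(np.clip(p_hat, EPS, 1.0))).sum())


class ReduceLROnPlateau:
    """Decay the learning rate by ``factor`` after ``patience``
    consecutive epochs without strict improvement of the monitored
    quantity (validation macro recall); improvement resets the counter."""

    def __init__(self, initial_lr: float, factor: float = 0.8, patience: int = 3) -> None:
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.best = -np.inf
        self.wait = 0

    def step(self, monitored: float) -> float:
        if monitored > self.best:
            self.best = monitored
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr *= self.factor
                self.wait = 0
        return self.lr


def lr_schedule_step(state: ReduceLROnPlateau, epoch_val_recall: float) -> float:
    """Functional wrapper over ``ReduceLROnPlateau.step``."""
    return state.step(epoch_val_recall)


def macro_recall(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(recall_score(y_true, y_pred, average="macro", zero_division=0))


def _predict(model: TCSCNN | ADMIL, inputs, batch_size: int = 32) -> np.ndarray:
    """Class probabilities in eval mode."""
    if isinstance(model, ADMIL):
        probs = [softmax(model.forward_bag(bag, training=False)[0]) for bag in inputs]
        return np.stack(probs)
    out = []
    for i in range(0, len(inputs), batch_size):
        logits = model.forward_logits(np.asarray(inputs[i : i + batch_size], dtype=float))
        out.append(softmax(logits, axis=1))
    return np.concatenate(out)


def _eval_loss(probs: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    p_true = np.clip(probs[np.arange(len(y)), y], EPS, 1.0)
    return float(np.mean(w[y] * -np.log(p_true)))


def _take(inputs, idx):
    if isinstance(inputs, np.ndarray):
        return inputs[idx]
    return [inputs[i] for i in idx]


def fit(
    model: TCSCNN | ADMIL,
    train_data: tuple,
    val_data: tuple,
    config: TrainConfig = TrainConfig(),
    class_weights: np.ndarray | None = None,
) -> tuple[TCSCNN | ADMIL, TrainHistory]:
    """Train with Adam and WCE; return (best model, history).

    ``train_data``/``val_data`` are ``(X, y)`` where X is an image array
    for the patch classifier or a list of bags for the MIL model. The
    best model is the checkpoint with maximal validation macro recall;
    all randomness (shuffling; dropout via the model's own stream)
    derives from seeds.
    """
    X_train, y_train = train_data
    X_val, y_val = val_data
    n = len(y_train)
    if n == 0:
        raise ValueError("empty training set")
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    num_classes = getattr(model.config, "num_classes", 4)
    w = np.ones(num_classes) if class_weights is None else np.asarray(class_weights, dtype=float)

    optimizer = Adam(model.param_slots(), lr=config.initial_lr)
    scheduler = ReduceLROnPlateau(config.initial_lr, config.lr_factor, config.lr_patience)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_recall = -np.inf
    best_state = model.get_state()

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        train_preds = np.zeros(n, dtype=int)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = _take(X_train, idx)
            if isinstance(model, TCSCNN):
                xb = np.asarray(xb, dtype=float)
            model.zero_grads()
            loss, probs = model.loss_and_grad(xb, y_train[idx], class_weights=w, training=True)
            model.apply_l2()
            optimizer.step()
            epoch_loss += loss * len(idx)
            train_preds[idx] = probs.argmax(axis=1)

        val_probs = _predict(model, X_val)
        val_pred = val_probs.argmax(axis=1)
        v_recall = macro_recall(y_val, val_pred)
        history.train_loss.append(epoch_loss / n)
        history.val_loss.append(_eval_loss(val_probs, y_val, w))
        history.train_recall.append(macro_recall(y_train, train_preds))
        history.val_recall.append(v_recall)
        if v_recall > best_recall:
            best_recall = v_recall
            best_state = model.get_state()
            history.best_epoch = epoch
        optimizer.lr = scheduler.step(v_recall)
        history.lr.append(optimizer.lr)

    best_model = copy.deepcopy(model)
    best_model.set_state(best_state)
    return best_model, history
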