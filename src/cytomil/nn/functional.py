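"""Stateless numeric primitives shared by the layers and the models."""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable (max-shifted) softmax along ``axis``.

    Raises ``ValueError`` on an empty axis: a softmax over zero entries
    has no meaning.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[axis] == 0:
        raise ValueError("softmax over an empty axis")
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He (variance-scaled) normal initialization, suited to ReLU stacks."""
    if fan_in <= 0:
        raise ValueError("fan_in must be positive")
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min(initial=0) < 0 or (labels.size and labels.max() >= num_classes):
        raise ValueError("labels out of range for one-hot encoding")
    out = np.zeros((labels.size, num_classes), dtype=float)
    out[np.arange(labels.size), labels] = 1.0
    return out
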