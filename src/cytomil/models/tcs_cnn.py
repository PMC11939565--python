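"""Task-specific CNN for 4-category cytopathology patch classification.

Architecture: five conv blocks (3x3 conv, stride 1, same padding -> ReLU
-> 2x2 max pool), global average pooling, two hidden fully connected
layers with ReLU and dropout (the second one produces the penultimate
embedding ``Z``), and a linear head feeding a 4-way softmax. All conv
and FC weights use He initialization; L2 regularization and dropout are
applied to the fully connected layers only.

On a 256x256 input the spatial trace is 256 -> 128 -> 64 -> 32 -> 16 -> 8,
so global average pooling acts on 8x8 maps. Smaller square inputs
(e.g. 64 or 32 pixels) follow the same halving trace; they are used for
reduced-scale experiments on synthetic data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from cytomil.nn.functional import softmax
from cytomil.nn.layers import Conv2D, Dense, Dropout, GlobalAvgPool, MaxPool2D, ReLU

#: channel range the architecture was dimensioned for; configurations
#: outside it are allowed (reduced-scale profiles) but not default.
STABLE_CHANNEL_RANGE = (64, 512)


@dataclass(frozen=True)
class TCSCNNConfig:
    """Hyperparameters of the patch classifier.

    ``conv_channels`` must have exactly five entries (one per conv
    block). ``fc_sizes`` are the two hidden FC widths; the second one is
    the dimension of the penultimate embedding Z (256 by default).
    """

    conv_channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    fc_sizes: tuple[int, ...] = (512, 256)
    num_classes: int = 4
    dropout_rate: float = 0.5
    l2_coefficient: float = 1e-4
    input_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 5:
            raise ValueError("conv_channels must have exactly 5 entries")
        if any(c <= 0 for c in self.conv_channels):
            raise ValueError("conv channel counts must be positive")
        if len(self.fc_sizes) != 2 or any(s <= 0 for s in self.fc_sizes):
            raise ValueError("fc_sizes must be two positive widths")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_coefficient < 0:
            raise ValueError("l2_coefficient must be nonnegative")
        if self.input_size <= 0 or self.input_size % 32 != 0:
            raise ValueError("input_size must be a positive multiple of 32")

    @property
    def embedding_dim(self) -> int:
        return self.fc_sizes[-1]


@dataclass
class PredictionRecord:
    """Per-patch prediction: class probabilities, penultimate embedding
    Z, and the argmax class (ties break to the lowest class index)."""

    probabilities: np.ndarray
    z: np.ndarray
    predicted_class: int


class TCSCNN:
    """The patch classifier with explicit forward and backward passes."""

    def __init__(self, config: TCSCNNConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = (3,) + tuple(config.conv_channels)
        self.blocks: list = []
        for i in range(5):
            self.blocks += [Conv2D(chans[i], chans[i + 1], 3, rng=rng), ReLU(), MaxPool2D(2)]
        self.gap = GlobalAvgPool()
        fc1, zdim = config.fc_sizes
        self.fc_layers = [
            Dense(config.conv_channels[-1], fc1, rng=rng),
            ReLU(),
            Dropout(config.dropout_rate, rng=rng),
            Dense(fc1, zdim, rng=rng),
            ReLU(),
            Dropout(config.dropout_rate, rng=rng),
        ]
        self.head = Dense(zdim, config.num_classes, rng=rng)
        self._z: np.ndarray | None = None
        self._conv_cache: np.ndarray | None = None

    # ---- layer bookkeeping -------------------------------------------------

    def _all_layers(self) -> list:
        return self.blocks + [self.gap] + self.fc_layers + [self.head]

    def param_slots(self) -> list[tuple[dict, dict, str]]:
        slots = []
        for layer in self._all_layers():
            for key in layer.params:
                slots.append((layer.params, layer.grads, key))
        return slots

    def zero_grads(self) -> None:
        for layer in self._all_layers():
            layer.zero_grads()

    def apply_l2(self) -> None:
        """Add the gradient of the L2 penalty (FC layers only)."""
        lam = self.config.l2_coefficient
        if lam == 0:
            return
        for layer in self.fc_layers + [self.head]:
            if "W" in layer.params:
                layer.grads["W"] += 2.0 * lam * layer.params["W"]

    def l2_penalty(self) -> float:
        lam = self.config.l2_coefficient
        total = 0.0
        for layer in self.fc_layers + [self.head]:
            if "W" in layer.params:
                total += float(np.sum(layer.params["W"] ** 2))
        return lam * total

    def num_params(self) -> int:
        return sum(p[k].size for p, _, k in self.param_slots())

    def get_state(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(layer.params) for layer in self._all_layers()]

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, params in zip(self._all_layers(), state, strict=True):
            for k in layer.params:
                layer.params[k][...] = params[k]

    # ---- forward / backward ------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        s = self.config.input_size
        if x.ndim != 4 or x.shape[1:] != (s, s, 3):
            raise ValueError(f"expected input of shape (B, {s}, {s}, 3), got {x.shape}")
        return x

    def forward_logits(
        self, x: np.ndarray, training: bool = False, keep_conv: bool = False
    ) -> np.ndarray:
        """Full forward pass; caches the penultimate Z (and optionally
        the final conv activation for Grad-CAM)."""
        x = self._check_input(x)
        for i, layer in enumerate(self.blocks):
            x = layer.forward(x, training=training)
            if keep_conv and i == len(self.blocks) - 2:  # ReLU of block 5
                self._conv_cache = x
        x = self.gap.forward(x, training=training)
        for layer in self.fc_layers:
            x = layer.forward(x, training=training)
        self._z = x
        return self.head.forward(x, training=training)

    def forward_embedding(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Penultimate embedding Z for a batch (used as the MIL feature
        extractor)."""
        self.forward_logits(x, training=training)
        return self._z

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dlogits)
        return self.backward_from_embedding(dy)

    def backward_from_embedding(self, dz: np.ndarray) -> np.ndarray:
        dy = dz
        for layer in reversed(self.fc_layers):
            dy = layer.backward(dy)
        dy = self.gap.backward(dy)
        for layer in reversed(self.blocks):
            dy = layer.backward(dy)
        return dy

    def backward_to_last_conv(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of a scalar in logit space w.r.t. the final conv
        activation (the ReLU output of block 5). Requires the previous
        forward to have been called with ``keep_conv=True``."""
        if self._conv_cache is None:
            raise RuntimeError("forward_logits(..., keep_conv=True) must run first")
        dy = self.head.backward(dlogits)
        for layer in reversed(self.fc_layers):
            dy = layer.backward(dy)
        dy = self.gap.backward(dy)
        dy = self.blocks[-1].backward(dy)  # pool of block 5
        return dy

    @property
    def last_conv_activation(self) -> np.ndarray:
        if self._conv_cache is None:
            raise RuntimeError("no cached conv activation")
        return self._conv_cache

    # ---- losses ------------------------------------------------------------

    def loss_and_grad(
        self,
        x: np.ndarray,
        y: np.ndarray,
        class_weights: np.ndarray | None = None,
        training: bool = True,
    ) -> tuple[float, np.ndarray]:
        """Mean per-sample weighted cross-entropy over the batch, with
        gradients accumulated into the layers. Returns (loss, probs)."""
        logits = self.forward_logits(x, training=training)
        probs = softmax(logits, axis=1)
        n, c = probs.shape
        w = np.ones(c) if class_weights is None else np.asarray(class_weights, dtype=float)
        wi = w[y]
        p_true = np.clip(probs[np.arange(n), y], 1e-7, 1.0)
        loss = float(np.mean(wi * -np.log(p_true)))
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y] = 1.0
        dlogits = wi[:, None] * (probs - onehot) / n
        self.backward(dlogits)
        return loss, probs


def build_tcs_cnn(config: TCSCNNConfig | None = None) -> TCSCNN:
    """Construct a TCS-CNN from a config (default config if omitted)."""
    return TCSCNN(config or TCSCNNConfig())


def forward_patch(model: TCSCNN, patch: np.ndarray) -> PredictionRecord:
    """Classify one normalized patch; returns probabilities, the
    penultimate embedding Z, and the predicted class (argmax, ties to
    the lowest index)."""
    patch = np.asarray(patch, dtype=float)
    if patch.min() < 0.0 or patch.max() > 1.0:
        raise ValueError("patch must be normalized to [0, 1]")
    logits = model.forward_logits(patch[None] if patch.ndim == 3 else patch)
    p = softmax(logits, axis=1)[0]
    return PredictionRecord(probabilities=p, z=model._z[0].copy(), predicted_class=int(np.argmax(p)))
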