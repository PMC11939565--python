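"""Attention-based deep multiple-instance-learning bag classifier.

The 16 instances of a bag are embedded by a shared (weight-tied) patch
CNN backbone; a gated attention network scores each instance,

    a_n = softmax_n( w^T ( tanh(V h_n) * sigmoid(U h_n) ) ),

the bag embedding is the attention-weighted average z = sum_n a_n h_n,
and a linear head with softmax produces bag-class probabilities. By
default the zero-padded slots participate in attention exactly like
real instances (their embeddings are whatever the backbone produces for
a zero image); an optional mask-out mode excludes absent slots from the
attention softmax.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from cytomil.data import Bag
from cytomil.models.tcs_cnn import TCSCNN, TCSCNNConfig
from cytomil.nn.functional import he_normal, sigmoid, softmax
from cytomil.nn.layers import Dense


@dataclass
class GatedAttentionParams:
    """Attention parameters: w (L,), V (L,D), U (L,D)."""

    w: np.ndarray
    V: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        L = self.w.shape[0]
        if self.V.shape[0] != L or self.U.shape[0] != L or self.V.shape != self.U.shape:
            raise ValueError("inconsistent attention parameter shapes")

    @property
    def hidden_dim(self) -> int:
        return self.w.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.V.shape[1]


@dataclass
class BagPrediction:
    """Bag-level output: class probabilities, the 16 attention scores
    (positive, summing to 1), and the bag embedding z."""

    probabilities: np.ndarray
    attention: np.ndarray
    z: np.ndarray
    predicted_class: int


def gated_attention(H: np.ndarray, params: GatedAttentionParams, mask: np.ndarray | None = None) -> np.ndarray:
    """Gated attention weights over the rows of H (N, D); max-shifted
    softmax. With a boolean ``mask``, absent rows get zero weight."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("H must be a nonempty (N, D) matrix")
    t = np.tanh(H @ params.V.T)  # (N, L)
    r = sigmoid(H @ params.U.T)  # (N, L)
    s = (t * r) @ params.w  # (N,)
    if mask is not None:
        if not np.any(mask):
            raise ValueError("mask excludes every instance")
        s = np.where(mask, s, -np.inf)
        shifted = s - s.max()
        e = np.where(mask, np.exp(shifted), 0.0)
        return e / e.sum()
    return softmax(s)


def pool(H: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention pooling z = sum_n a_n h_n."""
    return np.asarray(a, dtype=float) @ np.asarray(H, dtype=float)


class AttentionPool:
    """Gated attention + pooling with a hand-derived backward pass."""

    def __init__(self, feature_dim: int, hidden_dim: int, rng: np.random.Generator) -> None:
        self.params = {
            "w": he_normal(rng, (hidden_dim,), hidden_dim),
            "V": he_normal(rng, (hidden_dim, feature_dim), feature_dim),
            "U": he_normal(rng, (hidden_dim, feature_dim), feature_dim),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def as_params(self) -> GatedAttentionParams:
        return GatedAttentionParams(w=self.params["w"], V=self.params["V"], U=self.params["U"])

    def forward(self, H: np.ndarray, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        self._H = np.asarray(H, dtype=float)
        self._mask = mask
        self._t = np.tanh(self._H @ self.params["V"].T)
        self._r = sigmoid(self._H @ self.params["U"].T)
        s = (self._t * self._r) @ self.params["w"]
        if mask is not None:
            s = np.where(mask, s, -np.inf)
            shifted = s - s.max()
            e = np.where(mask, np.exp(shifted), 0.0)
            self._a = e / e.sum()
        else:
            self._a = softmax(s)
        z = self._a @ self._H
        return z, self._a

    def backward(self, dz: np.ndarray) -> np.ndarray:
        H, a, t, r, w = self._H, self._a, self._t, self._r, self.params["w"]
        e = H @ dz  # dL/da
        ds = a * (e - a @ e)  # softmax Jacobian (masked rows have a=0 => ds=0)
        gated = t * r
        self.grads["w"] += gated.T @ ds
        dt = ds[:, None] * (w[None, :] * r)
        dr = ds[:, None] * (w[None, :] * t)
        dV_in = dt * (1.0 - t * t)  # grad wrt (V h_n)
        dU_in = dr * r * (1.0 - r)  # grad wrt (U h_n)
        self.grads["V"] += dV_in.T @ H
        self.grads["U"] += dU_in.T @ H
        dH = dV_in @ self.params["V"] + dU_in @ self.params["U"]
        dH += np.outer(a, dz)
        return dH


@dataclass(frozen=True)
class MILConfig:
    backbone: TCSCNNConfig = field(
        default_factory=lambda: TCSCNNConfig()
    )
    attention_dim: int = 128  # L
    num_classes: int = 4
    mask_padded: bool = False  # True => exclude absent slots from attention
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attention_dim <= 0:
            raise ValueError("attention_dim must be positive")


class ADMIL:
    """Bag classifier: shared TCS-CNN backbone -> gated attention
    pooling -> linear head -> softmax. Trained end to end."""

    def __init__(self, config: MILConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = TCSCNN(config.backbone)
        D = config.backbone.embedding_dim
        self.attention = AttentionPool(D, config.attention_dim, rng)
        self.head = Dense(D, config.num_classes, rng=rng)

    def param_slots(self) -> list[tuple[dict, dict, str]]:
        slots = self.backbone.param_slots()
        for key in self.attention.params:
            slots.append((self.attention.params, self.attention.grads, key))
        for key in self.head.params:
            slots.append((self.head.params, self.head.grads, key))
        return slots

    def zero_grads(self) -> None:
        self.backbone.zero_grads()
        self.attention.zero_grads()
        self.head.zero_grads()

    def apply_l2(self) -> None:
        self.backbone.apply_l2()
        lam = self.config.backbone.l2_coefficient
        if lam:
            self.head.grads["W"] += 2.0 * lam * self.head.params["W"]

    def get_state(self) -> dict:
        return {
            "backbone": self.backbone.get_state(),
            "attention": copy.deepcopy(self.attention.params),
            "head": copy.deepcopy(self.head.params),
        }

    def set_state(self, state: dict) -> None:
        self.backbone.set_state(state["backbone"])
        for k in self.attention.params:
            self.attention.params[k][...] = state["attention"][k]
        for k in self.head.params:
            self.head.params[k][...] = state["head"][k]

    def _attention_mask(self, bag: Bag) -> np.ndarray | None:
        return bag.mask if self.config.mask_padded else None

    def forward_bag(self, bag: Bag, training: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (logits, attention, z) for one bag."""
        H = self.backbone.forward_embedding(bag.instances, training=training)
        z, a = self.attention.forward(H, mask=self._attention_mask(bag))
        logits = self.head.forward(z[None], training=training)[0]
        return logits, a, z

    def loss_and_grad(
        self,
        bags: list[Bag],
        y: np.ndarray,
        class_weights: np.ndarray | None = None,
        training: bool = True,
    ) -> tuple[float, np.ndarray]:
        """Mean weighted cross-entropy over a batch of bags; gradients
        are accumulated (forward+backward per bag, weight sharing across
        slots and bags)."""
        c = self.config.num_classes
        w = np.ones(c) if class_weights is None else np.asarray(class_weights, dtype=float)
        n = len(bags)
        probs = np.zeros((n, c))
        loss = 0.0
        for i, bag in enumerate(bags):
            logits, _, _ = self.forward_bag(bag, training=training)
            p = softmax(logits)
            probs[i] = p
            yi = int(y[i])
            loss += w[yi] * -np.log(max(p[yi], 1e-7))
            dlogits = p.copy()
            dlogits[yi] -= 1.0
            dlogits *= w[yi] / n
            dz = self.head.backward(dlogits[None])[0]
            dH = self.attention.backward(dz)
            self.backbone.backward_from_embedding(dH)
        return loss / n, probs


def extract_instance_embeddings(backbone: TCSCNN, bag: Bag) -> np.ndarray:
    """Instance embeddings H (16, D): the backbone's penultimate
    activation of every slot, parameters shared across slots."""
    return backbone.forward_embedding(bag.instances).copy()


def classify_bag(model: ADMIL, bag: Bag) -> BagPrediction:
    logits, a, z = model.forward_bag(bag, training=False)
    p = softmax(logits)
    return BagPrediction(
        probabilities=p,
        attention=a.copy(),
        z=z.copy(),
        predicted_class=int(np.argmax(p)),
    )
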