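"""Prediction introspection: softmax uncertainty measures, the
penultimate-embedding norm, Grad-CAM heatmaps for the patch CNN, and
4x4 attention-score maps for the MIL model.

The uncertainty triplet for a patch with class probabilities p and
penultimate embedding Z:

  * ``U_max = -max_i p_i``            (in [-1, -1/C]);
  * ``U_entropy = -sum_i p_i ln p_i`` (in [0, ln C], natural log);
  * ``||Z||``, the Euclidean norm — a proxy for how diagnostically
    salient the patch is to the trained features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from cytomil.data import Bag
from cytomil.models.tcs_cnn import TCSCNN
from cytomil.nn.functional import softmax


@dataclass
class UncertaintyRecord:
    u_max: float
    u_entropy: float
    z_norm: float


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a 1-D probability vector")
    if p.min() < -1e-9 or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must lie on the probability simplex")
    return p


def uncertainty_max(p: np.ndarray) -> float:
    """Negative maximum class probability."""
    return float(-_check_simplex(p).max())


def uncertainty_entropy(p: np.ndarray) -> float:
    """Shannon entropy of the class probabilities (natural log,
    0*log 0 := 0)."""
    p = _check_simplex(p)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def embedding_norm(z: np.ndarray) -> float:
    """Euclidean norm of the penultimate embedding."""
    return float(np.linalg.norm(np.asarray(z, dtype=float)))


def uncertainty_record(p: np.ndarray, z: np.ndarray) -> UncertaintyRecord:
    return UncertaintyRecord(
        u_max=uncertainty_max(p),
        u_entropy=uncertainty_entropy(p),
        z_norm=embedding_norm(z),
    )


def grad_cam(model: TCSCNN, patch: np.ndarray, target_class: int) -> np.ndarray:
    """Gradient-weighted class activation map for one patch.

    Channel weights are the spatial means of the gradient of the
    target class's pre-softmax score w.r.t. the final conv feature
    maps; the map is ReLU(sum_k weight_k * map_k), bilinearly upsampled
    to the patch size and min-max normalized to [0, 1] (an all-zero map
    stays all-zero).
    """
    c = model.config.num_classes
    if not 0 <= target_class < c:
        raise ValueError(f"invalid class id {target_class!r}")
    patch = np.asarray(patch, dtype=float)
    x = patch[None] if patch.ndim == 3 else patch
    logits = model.forward_logits(x, training=False, keep_conv=True)
    seed = np.zeros_like(logits)
    seed[0, target_class] = 1.0
    model.zero_grads()
    d_conv = model.backward_to_last_conv(seed)  # (1, h, w, K)
    model.zero_grads()
    activ = model.last_conv_activation[0]
    weights = d_conv[0].mean(axis=(0, 1))  # (K,)
    cam = np.maximum((activ * weights[None, None, :]).sum(axis=-1), 0.0)
    side = x.shape[1]
    cam = resize(cam, (side, side), order=1, mode="edge", anti_aliasing=False)
    peak = cam.max()
    if peak > 0:
        cam = (cam - cam.min()) / (peak - cam.min())
    return cam


def attention_map(bag: Bag, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """4x4 attention grid plus a rendered overlay on the reassembled BP.

    Grid cell (r, c) holds the score of slot 4*r + c. The overlay blends
    a colormap of each cell's score over the corresponding tile of the
    reassembled big patch. Returns (grid, overlay uint8 RGB).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (16,):
        raise ValueError("expected 16 attention scores")
    if abs(scores.sum() - 1.0) > 1e-6:
        raise ValueError("attention scores must sum to 1")
    grid = scores.reshape(4, 4)
    s = bag.instances.shape[1]
    big = np.zeros((4 * s, 4 * s, 3), dtype=float)
    for n in range(16):
        r, c = divmod(n, 4)
        big[r * s : (r + 1) * s, c * s : (c + 1) * s] = bag.instances[n]
    cmap = colormaps["jet"]
    rel = grid / grid.max() if grid.max() > 0 else grid
    overlay = big.copy()
    for n in range(16):
        r, c = divmod(n, 4)
        color = np.array(cmap(rel[r, c])[:3])
        cell = overlay[r * s : (r + 1) * s, c * s : (c + 1) * s]
        overlay[r * s : (r + 1) * s, c * s : (c + 1) * s] = 0.6 * cell + 0.4 * color
    return grid, (np.clip(overlay, 0, 1) * 255).astype(np.uint8)


def uncertainty_table(records: list[tuple[str, int, np.ndarray, np.ndarray]]):
    """Rows (patch id, predicted class, confidence, u_max, u_entropy,
    z_norm) from (id, predicted class, probabilities, Z) tuples."""
    import pandas as pd

    rows = []
    for patch_id, pred, p, z in records:
        rec = uncertainty_record(p, z)
        rows.append(
            {
                "patch_id": patch_id,
                "predicted_class": pred,
                "confidence": float(np.max(p)),
                "u_max": rec.u_max,
                "u_entropy": rec.u_entropy,
                "z_norm": rec.z_norm,
            }
        )
    return pd.DataFrame(rows)
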