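"""Reduced-scale experiment profiles on synthetic data.

The full-scale protocol (256x256 patches, 64-512 conv channels,
50 epochs) is sized for a GPU and a six-figure patch count. These
profiles are the package's CPU-scale counterparts for end-to-end runs
on the synthetic generator: 64x64 tiles rendered as downscaled views of
the standard 256x256 field, narrower conv stacks, and a higher initial
learning rate (1e-3) appropriate to the smaller parameterization and
sample size. Everything else (batch size 8, plateau decay 0.8 with
patience 3, weighted cross-entropy, best-recall checkpointing) follows
the standard protocol.
"""

from __future__ import annotations

import numpy as np

from cytomil.data import SplitSpec, compute_class_weights, stratified_split
from cytomil.models.admil import ADMIL, MILConfig
from cytomil.models.tcs_cnn import TCSCNN, TCSCNNConfig
from cytomil.synthetic import SyntheticSpec, generate_bag_dataset, generate_patch_dataset
from cytomil.training import TrainConfig, TrainHistory, fit

REDUCED_TILE = 64


def reduced_patch_config(seed: int = 0) -> TCSCNNConfig:
    return TCSCNNConfig(
        conv_channels=(8, 16, 32, 32, 32),
        fc_sizes=(64, 32),
        input_size=REDUCED_TILE,
        dropout_rate=0.25,
        l2_coefficient=1e-4,
        seed=seed,
    )


def reduced_mil_config(seed: int = 0) -> MILConfig:
    backbone = TCSCNNConfig(
        conv_channels=(4, 8, 16, 16, 16),
        fc_sizes=(32, 16),
        input_size=REDUCED_TILE,
        dropout_rate=0.1,
        l2_coefficient=1e-4,
        seed=seed,
    )
    return MILConfig(backbone=backbone, attention_dim=16, seed=seed + 1)


def train_reduced_patch_classifier(
    seed: int = 0,
    n_per_class: int = 120,
    epochs: int = 20,
) -> dict:
    """Generate ~4 * n_per_class synthetic small patches, split 8:2
    stratified, and train the reduced patch CNN. Returns the best model,
    history, and the held-out data with ground-truth blob centers."""
    spec = SyntheticSpec(seed=seed)
    X, y, centers = generate_patch_dataset(spec, n_per_class, seed=seed + 100, size=REDUCED_TILE)
    X = X.astype(np.float32) / 255.0
    tr, va = stratified_split(y, SplitSpec(seed=seed + 1))
    weights = compute_class_weights(np.bincount(y[tr], minlength=4))
    model = TCSCNN(reduced_patch_config(seed + 2))
    config = TrainConfig(epochs=epochs, batch_size=8, initial_lr=1e-3, seed=seed + 3)
    best, history = fit(model, (X[tr], y[tr]), (X[va], y[va]), config, class_weights=weights)
    return {
        "model": best,
        "history": history,
        "X_val": X[va],
        "y_val": y[va],
        "centers_val": [centers[i] for i in va],
        "X_train": X[tr],
        "y_train": y[tr],
        "class_weights": weights,
    }


def train_reduced_mil(
    seed: int = 0,
    n_bags_per_class: int = 24,
    n_signal: int = 4,
    epochs: int = 20,
) -> dict:
    """Generate synthetic bags (class-0 bags empty, others with
    ``n_signal`` signal slots), train the reduced AD-MIL end to end, and
    return the best model plus the bags with ground-truth signal slots."""
    spec = SyntheticSpec(seed=seed)
    bags, labels, signals = generate_bag_dataset(
        spec, n_bags_per_class, n_signal=n_signal, seed=seed + 200, size=REDUCED_TILE
    )
    tr, va = stratified_split(labels, SplitSpec(seed=seed + 1))
    weights = compute_class_weights(np.bincount(labels[tr], minlength=4))
    model = ADMIL(reduced_mil_config(seed + 2))
    config = TrainConfig(epochs=epochs, batch_size=8, initial_lr=1e-3, seed=seed + 3)
    best, history = fit(
        model,
        ([bags[i] for i in tr], labels[tr]),
        ([bags[i] for i in va], labels[va]),
        config,
        class_weights=weights,
    )
    return {
        "model": best,
        "history": history,
        "bags": bags,
        "labels": labels,
        "signal_slots": signals,
        "val_ids": va,
    }
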