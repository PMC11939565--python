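"""Dataset assembly: class weights, stratified partitioning, MIL bags.

A *bag* is the 16-slot container holding the small patches (SPs) of one
big patch (BP). Slots whose SP was filtered out are padded with an
all-zero matrix and flagged absent in the presence mask; the bag label
is the BP label.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

N_INSTANCES = 16  # a 1024x1024 BP tiles into 16 256x256 SPs


@dataclass
class Bag:
    """16-slot instance container for one big patch."""

    bag_id: str
    instances: np.ndarray  # (16, s, s, 3) float, values in [0, 1]
    mask: np.ndarray  # (16,) bool; False => slot is zero-padded
    label: int

    def __post_init__(self) -> None:
        if self.instances.shape[0] != N_INSTANCES or self.mask.shape != (N_INSTANCES,):
            raise ValueError(f"a bag must have exactly {N_INSTANCES} slots")
        if self.label not in (0, 1, 2, 3):
            raise ValueError("bag label must be a class id 0-3")


@dataclass(frozen=True)
class ClassCounts:
    """Per-class sample counts N_j with total M and C classes."""

    counts: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def num_classes(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    k: int = 5
    seed: int = 0
    granularity: str = "patch"  # "patch" | "slide"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.granularity not in ("patch", "slide"):
            raise ValueError("granularity must be 'patch' or 'slide'")


def compute_class_weights(counts: ClassCounts | tuple[int, ...] | list[int]) -> np.ndarray:
    """Inverse-frequency class weights w_j = M / (N_j * C).

    With these weights the identity sum_j w_j * N_j = M holds exactly,
    and balanced counts give all weights equal to 1.
    """
    if not isinstance(counts, ClassCounts):
        counts = ClassCounts(tuple(int(c) for c in counts))
    if any(n <= 0 for n in counts.counts):
        raise ValueError("every class count must be positive for weight computation")
    m, c = counts.total, counts.num_classes
    return np.array([m / (n * c) for n in counts.counts], dtype=float)


def stratified_split(
    labels: np.ndarray | list[int],
    spec: SplitSpec = SplitSpec(),
    groups: np.ndarray | list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/validation split of indices 0..n-1.

    Patch granularity stratifies individual samples; slide granularity
    (``groups`` required: one slide id per sample) keeps all samples of
    a slide on one side, stratifying slides by their label. A class with
    a single member goes to the training side with a warning.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    if spec.granularity == "slide":
        if groups is None:
            raise ValueError("slide-level split requires per-sample group ids")
        groups = np.asarray(groups)
        uniq, first = np.unique(groups, return_index=True)
        slide_labels = labels[first]
        tr_slides, va_slides = stratified_split(
            slide_labels, SplitSpec(spec.train_fraction, spec.k, spec.seed, "patch")
        )
        tr_set = set(uniq[tr_slides])
        idx = np.arange(labels.size)
        in_train = np.isin(groups, list(tr_set))
        return idx[in_train], idx[~in_train]

    train_ids: list[np.ndarray] = []
    val_ids: list[np.ndarray] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if members.size == 1:
            warnings.warn(f"class {cls} has a single member; forcing it to train")
            train_ids.append(members)
            continue
        perm = rng.permutation(members)
        n_train = int(round(spec.train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_ids.append(np.sort(perm[:n_train]))
        val_ids.append(np.sort(perm[n_train:]))
    train = np.sort(np.concatenate(train_ids)) if train_ids else np.array([], dtype=int)
    val = np.sort(np.concatenate(val_ids)) if val_ids else np.array([], dtype=int)
    return train, val


def stratified_kfold(
    labels: np.ndarray | list[int], spec: SplitSpec = SplitSpec()
) -> list[np.ndarray]:
    """k disjoint stratified folds (validation index sets) covering all
    samples; per-class fold sizes differ by at most one."""
    labels = np.asarray(labels)
    _, min_count = np.unique(labels, return_counts=True)
    if spec.k > min_count.min():
        raise ValueError("k must not exceed the smallest class size")
    skf = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
    return [val for _, val in skf.split(np.zeros(labels.size), labels)]


def build_bags(
    tile_manifest: pd.DataFrame,
    images: dict[str, np.ndarray] | None = None,
    root: str | Path | None = None,
) -> list[Bag]:
    """Assemble one bag per big patch that kept at least one tile.

    ``tile_manifest`` needs columns: path, slide_id, bp_row, bp_col,
    sp_index, label, retained. Retained tiles are loaded (from
    ``images`` keyed by path, or from disk), normalized to [0, 1] and
    placed at their sp_index; the remaining slots are exact zeros with
    mask=False. A BP whose tiles were all filtered emits no bag.
    """
    required = {"path", "slide_id", "bp_row", "bp_col", "sp_index", "label", "retained"}
    missing = required - set(tile_manifest.columns)
    if missing:
        raise ValueError(f"tile manifest missing columns: {sorted(missing)}")

    bags: list[Bag] = []
    for (slide, row, col), group in tile_manifest.groupby(
        ["slide_id", "bp_row", "bp_col"], sort=True
    ):
        kept = group[group["retained"].astype(bool)]
        if kept.empty:
            logger.info("BP %s/(%s,%s): all tiles filtered, no bag emitted", slide, row, col)
            continue
        labels = set(group["label"].astype(int))
        if len(labels) != 1:
            raise ValueError(f"BP {slide}/({row},{col}) has inconsistent tile labels")
        first = _load_tile(kept.iloc[0]["path"], images, root)
        s = first.shape[0]
        inst = np.zeros((N_INSTANCES, s, s, 3), dtype=np.float32)
        mask = np.zeros(N_INSTANCES, dtype=bool)
        for _, rec in kept.iterrows():
            n = int(rec["sp_index"])
            inst[n] = _load_tile(rec["path"], images, root)
            mask[n] = True
        bags.append(
            Bag(bag_id=f"{slide}_bp{row}_{col}", instances=inst, mask=mask, label=labels.pop())
        )
    return bags


def _load_tile(path: str, images: dict[str, np.ndarray] | None, root: str | Path | None) -> np.ndarray:
    if images is not None and path in images:
        arr = images[path]
    else:
        full = Path(root) / path if root is not None else Path(path)
        arr = np.asarray(Image.open(full).convert("RGB"))
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    return arr.astype(np.float32)


def save_bag_index(bags: list[Bag], tile_manifest: pd.DataFrame, path: str | Path) -> None:
    """JSON index: bag id -> slot -> tile path (absent slots omitted)."""
    lookup = {
        (r.slide_id, int(r.bp_row), int(r.bp_col), int(r.sp_index)): r.path
        for r in tile_manifest.itertuples()
        if bool(r.retained)
    }
    index = {}
    for bag in bags:
        slide, bp = bag.bag_id.rsplit("_bp", 1)
        row, col = (int(v) for v in bp.split("_"))
        index[bag.bag_id] = {
            str(n): lookup[(slide, row, col, n)] for n in range(N_INSTANCES) if bag.mask[n]
        }
    Path(path).write_text(json.dumps(index, indent=1))
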