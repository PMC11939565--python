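"""Seeded synthetic cytology-like image generator with exact ground truth.

Real fine-needle-aspiration slides show dark, hematoxylin-stained
nuclear material on a bright background. The generator emulates the
features the downstream pipeline relies on — not stain photorealism:

  * class 0 (Nondiagnostic): near-empty fields with sparse small debris;
  * class 1 (Benign): regular round nuclei arranged in loose sheets;
  * class 2 (Follicular neoplasm): nuclei arranged on rings
    (microfollicle-like structures);
  * class 3 (Malignant): enlarged, irregular, overlapping nuclei.

Every blob center is returned alongside the image, so filtering rules,
classifier separability, attention recovery, and heatmap localization
can all be tested against exact ground truth. All randomness derives
from a per-call stream seeded by (seed, category, index), so datasets
are bit-reproducible and safe to generate in parallel.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import line, polygon

from cytomil.data import N_INSTANCES, Bag

CLASS_NAMES = ("Nondiagnostic", "Benign", "Follicular neoplasm", "Malignant")

#: saturated pen-mark colors (diagnostically irrelevant artifacts)
_PEN_COLORS = ((0, 90, 200), (0, 160, 60), (210, 30, 30))

#: dark nuclear stain base color (luma ~78, well below the 127 threshold)
_NUCLEUS_COLOR = np.array([90.0, 60.0, 140.0])


@dataclass(frozen=True)
class ClassMorphology:
    """Blob statistics for one class, per 256x256 tile."""

    nucleus_density: float  # expected blobs per 256x256 tile
    nucleus_radius_mean: float  # pixels
    nucleus_radius_sd: float
    irregularity: float  # 0-1 boundary perturbation amplitude
    cluster_tendency: float  # 0-1; 0 = uniform scatter
    arrangement: str  # "sparse" | "sheet" | "follicle" | "overlap"

    def __post_init__(self) -> None:
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if self.nucleus_radius_mean <= 0 or self.nucleus_radius_sd < 0:
            raise ValueError("radii must be positive")
        for name in ("irregularity", "cluster_tendency"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def default_morphologies() -> dict[int, ClassMorphology]:
    return {
        0: ClassMorphology(10.0, 5.0, 1.5, 0.20, 0.0, "sparse"),
        1: ClassMorphology(25.0, 6.0, 1.0, 0.10, 0.6, "sheet"),
        2: ClassMorphology(30.0, 5.0, 1.0, 0.15, 0.9, "follicle"),
        3: ClassMorphology(45.0, 9.0, 2.5, 0.60, 0.7, "overlap"),
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic generator."""

    image_size: int = 1024  # big-patch side, multiple of tile_size
    tile_size: int = 256  # small-patch side
    background_gray: int = 245
    background_noise: float = 3.0
    artifact_prob: float = 0.0  # per-tile pen-mark probability
    morphologies: dict[int, ClassMorphology] = field(default_factory=default_morphologies)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size % self.tile_size != 0:
            raise ValueError("image_size must be divisible by tile_size")
        if not 0 <= self.background_gray <= 255:
            raise ValueError("background_gray must be a uint8 level")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ValueError("artifact_prob must be in [0, 1]")

    def with_density(self, density: float) -> "SyntheticSpec":
        """Spec whose every class has the given nucleus density."""
        morphs = {k: replace(m, nucleus_density=density) for k, m in self.morphologies.items()}
        return replace(self, morphologies=morphs)


@dataclass
class BigPatchRecord:
    image: np.ndarray  # (S, S, 3) uint8
    slide_id: str
    bp_row: int
    bp_col: int
    label: int
    blob_centers: list[tuple[int, int]]  # (y, x), image coordinates
    artifact_tiles: list[int]  # sp_index of tiles that received a pen mark


def _rng_for(seed: int, category: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(category, index)))


def _blob_positions(morph: ClassMorphology, size: int, rng: np.random.Generator) -> np.ndarray:
    """Blob centers for one tile in 256x256 reference coordinates,
    following the class arrangement. Tiles of other sizes are rendered
    as rescaled views of the same field, so ``nucleus_density`` is the
    expected blob count per tile regardless of pixel size."""
    n = rng.poisson(morph.nucleus_density)
    if n == 0:
        return np.empty((0, 2))
    if morph.arrangement == "follicle":
        # nuclei on rings: microfollicle-like circular arrangements
        centers = []
        ring_r = 3.2 * morph.nucleus_radius_mean
        per_ring = max(5, int(round(2 * np.pi * ring_r / (2.2 * morph.nucleus_radius_mean))))
        remaining = n
        while remaining > 0:
            cy, cx = rng.uniform(ring_r, size - ring_r, size=2)
            k = min(per_ring, remaining)
            phase = rng.uniform(0, 2 * np.pi)
            angles = phase + np.linspace(0, 2 * np.pi, k, endpoint=False)
            jitter = rng.normal(0, 0.05 * ring_r, size=(k, 2))
            ring = np.stack([cy + ring_r * np.sin(angles), cx + ring_r * np.cos(angles)], axis=1)
            centers.append(ring + jitter)
            remaining -= k
        return np.concatenate(centers)
    if morph.cluster_tendency > 0 and morph.arrangement in ("sheet", "overlap"):
        n_clustered = rng.binomial(n, morph.cluster_tendency)
        scatter = rng.uniform(0, size, size=(n - n_clustered, 2))
        if n_clustered == 0:
            return scatter
        spread = (2.0 if morph.arrangement == "overlap" else 4.0) * morph.nucleus_radius_mean
        n_clusters = max(1, int(np.ceil(n_clustered / 8)))
        cluster_centers = rng.uniform(spread, size - spread, size=(n_clusters, 2))
        assign = rng.integers(0, n_clusters, size=n_clustered)
        clustered = cluster_centers[assign] + rng.normal(0, spread, size=(n_clustered, 2))
        return np.concatenate([scatter, clustered])
    return rng.uniform(0, size, size=(n, 2))


def _draw_blob(img: np.ndarray, cy: float, cx: float, radius: float, irregularity: float, rng: np.random.Generator) -> None:
    n_vert = 16
    angles = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
    radii = radius * (1.0 + irregularity * rng.uniform(-0.6, 0.6, size=n_vert))
    radii = np.maximum(radii, 1.0)
    rr, cc = polygon(cy + radii * np.sin(angles), cx + radii * np.cos(angles), shape=img.shape[:2])
    shade = _NUCLEUS_COLOR * rng.uniform(0.75, 1.15)
    img[rr, cc] = np.clip(shade, 0, 200)


def _draw_pen_mark(img: np.ndarray, rng: np.random.Generator) -> None:
    size = img.shape[0]
    color = _PEN_COLORS[rng.integers(0, len(_PEN_COLORS))]
    y0, x0 = rng.integers(0, size, size=2)
    y1, x1 = rng.integers(0, size, size=2)
    rr, cc = line(int(y0), int(x0), int(y1), int(x1))
    half = max(2, size // 64)
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            yy = np.clip(rr + dy, 0, size - 1)
            xx = np.clip(cc + dx, 0, size - 1)
            img[yy, xx] = color


def render_tile(
    spec: SyntheticSpec,
    category: int,
    rng: np.random.Generator,
    size: int | None = None,
    allow_artifact: bool = True,
) -> tuple[np.ndarray, list[tuple[int, int]], bool]:
    """One small patch: (image uint8, blob centers, has_artifact)."""
    if category not in spec.morphologies:
        raise ValueError(f"unknown category id: {category!r}")
    size = size or spec.tile_size
    morph = spec.morphologies[category]
    img = np.full((size, size, 3), float(spec.background_gray))
    if spec.background_noise > 0:
        img += rng.normal(0, spec.background_noise, size=img.shape)
    # positions are drawn in 256x256 reference coordinates; other tile
    # sizes render the same field rescaled
    positions = _blob_positions(morph, 256, rng)
    centers: list[tuple[int, int]] = []
    scale = size / 256.0
    for ry, rx in positions:
        cy, cx = ry * scale, rx * scale
        radius = max(1.5, rng.normal(morph.nucleus_radius_mean, morph.nucleus_radius_sd)) * scale
        _draw_blob(img, cy, cx, radius, morph.irregularity, rng)
        if 0 <= cy < size and 0 <= cx < size:
            centers.append((int(cy), int(cx)))
    has_artifact = False
    if allow_artifact and rng.random() < spec.artifact_prob:
        _draw_pen_mark(img, rng)
        has_artifact = True
    return np.clip(img, 0, 255).astype(np.uint8), centers, has_artifact


def generate_big_patch(
    spec: SyntheticSpec, category: int, seed: int, index: int = 0, slide_id: str = "synthetic"
) -> BigPatchRecord:
    """One big patch assembled from per-tile renders, with ground truth."""
    if category not in (0, 1, 2, 3):
        raise ValueError(f"unknown category id: {category!r}")
    rng = _rng_for(seed, category, index)
    g = spec.image_size // spec.tile_size
    img = np.zeros((spec.image_size, spec.image_size, 3), dtype=np.uint8)
    centers: list[tuple[int, int]] = []
    artifact_tiles: list[int] = []
    for r in range(g):
        for c in range(g):
            tile, tile_centers, artifact = render_tile(spec, category, rng)
            y0, x0 = r * spec.tile_size, c * spec.tile_size
            img[y0 : y0 + spec.tile_size, x0 : x0 + spec.tile_size] = tile
            centers += [(y0 + cy, x0 + cx) for cy, cx in tile_centers]
            if artifact:
                artifact_tiles.append(r * g + c)
    return BigPatchRecord(
        image=img,
        slide_id=slide_id,
        bp_row=index,
        bp_col=0,
        label=category,
        blob_centers=centers,
        artifact_tiles=artifact_tiles,
    )


def generate_dataset(
    spec: SyntheticSpec,
    n_big_patches_per_class: int | dict[int, int],
    seed: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write big-patch PNGs plus a manifest CSV (path, slide_id, bp_row,
    bp_col, label); returns the manifest."""
    if isinstance(n_big_patches_per_class, int):
        if n_big_patches_per_class < 1:
            raise ValueError("n_big_patches_per_class must be >= 1")
        counts = {c: n_big_patches_per_class for c in range(4)}
    else:
        counts = dict(n_big_patches_per_class)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for category, n in sorted(counts.items()):
        for i in range(n):
            rec = generate_big_patch(spec, category, seed, index=i, slide_id=f"slide{category}")
            name = f"bp_c{category}_{i:04d}.png"
            Image.fromarray(rec.image).save(out / name)
            rows.append(
                {
                    "path": name,
                    "slide_id": rec.slide_id,
                    "bp_row": rec.bp_row,
                    "bp_col": rec.bp_col,
                    "label": category,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def generate_patch_dataset(
    spec: SyntheticSpec,
    n_per_class: int,
    seed: int,
    size: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[list[tuple[int, int]]]]:
    """In-memory small-patch dataset: (X uint8 (N,s,s,3), labels,
    per-patch blob centers). Used for reduced-scale training runs."""
    size = size or spec.tile_size
    images, labels, centers = [], [], []
    for category in range(4):
        for i in range(n_per_class):
            rng = _rng_for(seed, category, i)
            img, ctr, _ = render_tile(spec, category, rng, size=size)
            images.append(img)
            labels.append(category)
            centers.append(ctr)
    return np.stack(images), np.array(labels), centers


def generate_mil_bag(
    spec: SyntheticSpec,
    n_signal: int,
    signal_category: int,
    seed: int,
    index: int = 0,
    size: int | None = None,
) -> tuple[Bag, list[int]]:
    """A bag with exactly ``n_signal`` slots carrying the signal class's
    morphology and the rest near-empty (class 0). Bag label is the
    signal class if any signal is present, else 0. Returns the bag and
    the sorted signal slot indices."""
    if not 0 <= n_signal <= N_INSTANCES:
        raise ValueError(f"n_signal must be in [0, {N_INSTANCES}]")
    if signal_category not in (0, 1, 2, 3):
        raise ValueError(f"unknown category id: {signal_category!r}")
    size = size or spec.tile_size
    rng = _rng_for(seed, signal_category, index)
    signal_slots = sorted(rng.choice(N_INSTANCES, size=n_signal, replace=False).tolist())
    inst = np.zeros((N_INSTANCES, size, size, 3), dtype=np.float32)
    for n in range(N_INSTANCES):
        category = signal_category if n in signal_slots else 0
        img, _, _ = render_tile(spec, category, rng, size=size)
        inst[n] = img.astype(np.float32) / 255.0
    label = signal_category if n_signal > 0 else 0
    bag = Bag(
        bag_id=f"synthbag_c{signal_category}_s{n_signal}_{index}",
        instances=inst,
        mask=np.ones(N_INSTANCES, dtype=bool),
        label=label,
    )
    return bag, signal_slots


def generate_bag_dataset(
    spec: SyntheticSpec,
    n_bags_per_class: int,
    n_signal: int,
    seed: int,
    size: int | None = None,
) -> tuple[list[Bag], np.ndarray, list[list[int]]]:
    """Bags for all four classes: class 0 bags carry no signal slots
    (all near-empty), classes 1-3 carry ``n_signal`` signal slots."""
    bags, labels, signals = [], [], []
    for category in range(4):
        k = 0 if category == 0 else n_signal
        for i in range(n_bags_per_class):
            bag, sig = generate_mil_bag(spec, k, category, seed, index=i, size=size)
            bags.append(bag)
            labels.append(bag.label)
            signals.append(sig)
    return bags, np.array(labels), signals


def manifest_checksum(manifest: pd.DataFrame, root: str | Path) -> str:
    """SHA-256 over manifest rows and the referenced image bytes."""
    h = hashlib.sha256()
    h.update(manifest.to_csv(index=False).encode())
    for p in manifest["path"]:
        h.update(Path(root, p).read_bytes())
    return h.hexdigest()
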