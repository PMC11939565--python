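"""Tiling and background filtering of slide rasters.

The pipeline mirrors standard cytopathology preprocessing: a slide (or
any large raster) is cut into non-overlapping 1024x1024 big patches
(BPs), each BP into 16 non-overlapping 256x256 small patches (SPs), and
tiles are kept only if at least 1% of their pixels are "black" after
grayscale conversion, blurring, and binary thresholding at 127. Tiles
named in an exclusion manifest (the stand-in for manual expert review)
are dropped afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

BLACK_THRESHOLD = 127
MIN_BLACK_RATIO = 0.01
#: ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class Tile:
    """One tile cut from a larger raster, with its grid position."""

    image: np.ndarray
    row: int
    col: int


@dataclass
class TileRecord:
    """A small patch with provenance, weak label, and filter state."""

    image: np.ndarray  # (s, s, 3) uint8
    slide_id: str
    bp_row: int
    bp_col: int
    sp_index: int  # 0-15, row-major within the BP
    label: int  # weak label inherited from the parent BP
    retained: bool = True
    black_ratio: float = 0.0

    @property
    def key(self) -> tuple[str, int, int, int]:
        return (self.slide_id, self.bp_row, self.bp_col, self.sp_index)


def tile(image: np.ndarray, tile_size: int) -> list[Tile]:
    """Non-overlapping, axis-aligned tiles with 0-based row-major grid
    coordinates (top-left origin). Partial border strips are dropped; an
    image smaller than the tile in either dimension yields no tiles."""
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    image = np.asarray(image)
    h, w = image.shape[:2]
    rows, cols = h // tile_size, w // tile_size
    if rows == 0 or cols == 0:
        logger.warning("image %sx%s smaller than tile size %s: no tiles", h, w, tile_size)
        return []
    out = []
    for r in range(rows):
        for c in range(cols):
            y0, x0 = r * tile_size, c * tile_size
            out.append(Tile(image[y0 : y0 + tile_size, x0 : x0 + tile_size], r, c))
    return out


def _opencv_like_sigma(kernel: int) -> float:
    # the conventional kernel-size -> sigma mapping for Gaussian smoothing
    return 0.3 * ((kernel - 1) * 0.5 - 1.0) + 0.8


def background_binary(
    tile_img: np.ndarray, blur_kernel: int = 5, threshold: int = BLACK_THRESHOLD
) -> np.ndarray:
    """Binary mask of "black" (dark, cellular) pixels.

    Grayscale uses BT.601 luma; blurring is Gaussian with a kernel-sized
    footprint (``blur_kernel == 1`` disables blur entirely); a pixel is
    black iff its blurred grayscale value is <= ``threshold``.
    """
    if blur_kernel < 1 or blur_kernel % 2 == 0:
        raise ValueError("blur_kernel must be odd and >= 1")
    img = np.asarray(tile_img, dtype=float)
    gray = img @ _LUMA if img.ndim == 3 else img
    if blur_kernel > 1:
        radius = (blur_kernel - 1) // 2
        gray = gaussian_filter(gray, sigma=_opencv_like_sigma(blur_kernel), radius=radius, mode="nearest")
    return gray <= threshold


def black_ratio(mask: np.ndarray) -> float:
    """Fraction of black pixels in a binary mask."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    return float(np.count_nonzero(mask)) / mask.size


def is_background(
    tile_img: np.ndarray,
    blur_kernel: int = 5,
    threshold: int = BLACK_THRESHOLD,
    min_ratio: float = MIN_BLACK_RATIO,
) -> bool:
    """True (discard) iff the black-pixel ratio is strictly below
    ``min_ratio``; a tile at exactly the boundary ratio is retained."""
    return black_ratio(background_binary(tile_img, blur_kernel, threshold)) < min_ratio


def apply_exclusions(
    tiles: Sequence[TileRecord], exclusion_manifest: Iterable[tuple[str, int, int, int]]
) -> list[TileRecord]:
    """Flag the listed tiles as not retained (manual-review stand-in);
    order is preserved and all records are returned."""
    excluded = set(tuple(e) for e in exclusion_manifest)
    unknown = excluded - {t.key for t in tiles}
    if unknown:
        raise ValueError(f"exclusion manifest names unknown tiles: {sorted(unknown)[:5]}")
    for t in tiles:
        if t.key in excluded:
            t.retained = False
    return list(tiles)


def normalize(tile_img: np.ndarray) -> np.ndarray:
    """uint8 image -> float in [0, 1] via exact division by 255."""
    return np.asarray(tile_img, dtype=np.float64) / 255.0


def extract_tile_records(
    bp_image: np.ndarray,
    slide_id: str,
    bp_row: int,
    bp_col: int,
    label: int,
    tile_size: int = 256,
    blur_kernel: int = 5,
    threshold: int = BLACK_THRESHOLD,
    min_ratio: float = MIN_BLACK_RATIO,
) -> list[TileRecord]:
    """Tile one BP into SPs, apply the background filter, and return the
    records (discarded tiles carry retained=False)."""
    tiles = tile(bp_image, tile_size)
    grid_cols = bp_image.shape[1] // tile_size
    records = []
    for t in tiles:
        mask = background_binary(t.image, blur_kernel, threshold)
        ratio = black_ratio(mask)
        records.append(
            TileRecord(
                image=np.ascontiguousarray(t.image),
                slide_id=slide_id,
                bp_row=bp_row,
                bp_col=bp_col,
                sp_index=t.row * grid_cols + t.col,
                label=label,
                retained=ratio >= min_ratio,
                black_ratio=ratio,
            )
        )
    return records


def process_manifest(
    bp_manifest: pd.DataFrame,
    root: str | Path,
    out_dir: str | Path,
    tile_size: int = 256,
    blur_kernel: int = 5,
    threshold: int = BLACK_THRESHOLD,
    min_ratio: float = MIN_BLACK_RATIO,
    image_format: str = "png",
    exclusions: Iterable[tuple[str, int, int, int]] = (),
) -> pd.DataFrame:
    """Run tiling + filtering over a BP manifest (columns: path,
    slide_id, bp_row, bp_col, label); write retained-tile images and a
    tile manifest CSV; return the manifest.

    PNG output is lossless and the default; JPEG (quality 95) is
    available to mirror common storage practice.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_records: list[TileRecord] = []
    for rec in bp_manifest.itertuples():
        img = np.asarray(Image.open(Path(root) / rec.path).convert("RGB"))
        all_records += extract_tile_records(
            img, rec.slide_id, int(rec.bp_row), int(rec.bp_col), int(rec.label),
            tile_size, blur_kernel, threshold, min_ratio,
        )
    apply_exclusions(all_records, exclusions)
    rows = []
    for t in all_records:
        name = f"{t.slide_id}_bp{t.bp_row}_{t.bp_col}_sp{t.sp_index:02d}.{image_format}"
        if t.retained:
            im = Image.fromarray(t.image)
            if image_format == "jpeg":
                im.save(out / name, quality=95)
            else:
                im.save(out / name)
        rows.append(
            {
                "path": name,
                "slide_id": t.slide_id,
                "bp_row": t.bp_row,
                "bp_col": t.bp_col,
                "sp_index": t.sp_index,
                "label": t.label,
                "retained": t.retained,
                "black_ratio": t.black_ratio,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "tile_manifest.csv", index=False)
    return manifest


def reassemble(tiles: Sequence[Tile], tile_size: int) -> np.ndarray:
    """Stitch tiles back into one image (inverse of ``tile`` for
    exactly divisible inputs)."""
    rows = max(t.row for t in tiles) + 1
    cols = max(t.col for t in tiles) + 1
    sample = tiles[0].image
    shape = (rows * tile_size, cols * tile_size) + sample.shape[2:]
    out = np.zeros(shape, dtype=sample.dtype)
    for t in tiles:
        out[t.row * tile_size : (t.row + 1) * tile_size, t.col * tile_size : (t.col + 1) * tile_size] = t.image
    return out
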