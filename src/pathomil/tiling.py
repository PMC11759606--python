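"""Slide tiling, background exclusion and Reinhard stain normalization.

A whole-slide image is processed as the largest grid of full, non-overlapping
``tile_size`` x ``tile_size`` squares anchored at the image origin; partial
edge tiles are discarded.  Tiles whose pixels are almost exclusively white are
treated as background (no tissue) and excluded.  Remaining tiles are colour
normalized with the Reinhard method: an affine per-channel match of mean and
standard deviation to a reference, carried out in the decorrelated Ruderman
l-alpha-beta space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

DEFAULT_TILE_SIZE = 512
DEFAULT_WHITE_LEVEL = 220
DEFAULT_WHITE_FRACTION = 0.8

# Ruderman RGB -> LMS transform and the lab rotation (Reinhard et al. 2001).
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float
)
_LAB2LMS = np.linalg.inv(_LMS2LAB)
_LOG_EPS = 1e-6


@dataclass
class Tile:
    """One square RGB patch cut from a slide at grid position (row, col)."""

    slide_id: str
    row: int
    col: int
    pixels: np.ndarray  # (size, size, 3) uint8

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] != p.shape[1]:
            raise ValueError(f"tile pixels must be square HxWx3, got {p.shape}")
        if self.row < 0 or self.col < 0:
            raise ValueError("tile grid coordinates must be non-negative")
        self.pixels = p.astype(np.uint8, copy=False)

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])


@dataclass
class ReinhardReference:
    """Target channel means/stds in Ruderman l-alpha-beta space."""

    mean_lab: np.ndarray
    std_lab: np.ndarray

    def __post_init__(self) -> None:
        self.mean_lab = np.asarray(self.mean_lab, dtype=float).reshape(3)
        self.std_lab = np.asarray(self.std_lab, dtype=float).reshape(3)
        if not np.all(self.std_lab > 0):
            raise ValueError("reference stds must be strictly positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"mean_lab": self.mean_lab.tolist(), "std_lab": self.std_lab.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ReinhardReference":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["mean_lab"]), np.asarray(d["std_lab"]))


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Map float/uint8 RGB (HxWx3) to Ruderman l-alpha-beta."""
    x = np.asarray(rgb, dtype=float) / 255.0
    lms = x @ _RGB2LMS.T
    log_lms = np.log10(np.maximum(lms, _LOG_EPS))
    return log_lms @ _LMS2LAB.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`; returns uint8 with clipping to [0, 255]."""
    log_lms = np.asarray(lab, dtype=float) @ _LAB2LMS.T
    lms = np.power(10.0, log_lms)
    rgb = lms @ _LMS2RGB.T
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def tile_image(image: np.ndarray, tile_size: int = DEFAULT_TILE_SIZE, slide_id: str = "slide") -> list[Tile]:
    """Cut ``image`` into the full non-overlapping tile grid anchored at (0, 0).

    Tiles are returned in row-major order; partial tiles at the right/bottom
    edges are discarded.  An image smaller than one tile yields an empty list
    (with a warning) rather than an error.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {img.shape}")
    n_rows, n_cols = img.shape[0] // tile_size, img.shape[1] // tile_size
    if n_rows == 0 or n_cols == 0:
        logger.warning(
            "image of shape %s is smaller than one %dpx tile; no tiles produced",
            img.shape, tile_size,
        )
        return []
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            block = img[r * tile_size:(r + 1) * tile_size, c * tile_size:(c + 1) * tile_size]
            tiles.append(Tile(slide_id, r, c, block))
    return tiles


def is_background(
    tile: Tile | np.ndarray,
    white_level: int = DEFAULT_WHITE_LEVEL,
    white_fraction: float = DEFAULT_WHITE_FRACTION,
) -> bool:
    """True iff the fraction of near-white pixels strictly exceeds ``white_fraction``.

    A pixel counts as white when all three channels are >= ``white_level``.
    """
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    white = np.all(pixels >= white_level, axis=-1)
    return bool(white.mean() > white_fraction)


def compute_reference(tile: Tile | np.ndarray) -> ReinhardReference:
    """Reference stats (lab means/stds) of one tile, with a degeneracy guard."""
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    lab = rgb_to_lab(pixels)
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    return ReinhardReference(mean, np.maximum(std, 1e-4))


def reinhard_normalize(tile: Tile, ref: ReinhardReference, _sigma_floor: float = 1e-8) -> Tile:
    """Affine-match the tile's l-alpha-beta channel stats to the reference.

    Each channel is rescaled as ``(x - mu_tile) * (sigma_ref / sigma_tile) +
    mu_ref``.  A (near-)constant channel has no defined scale; it is shifted
    only (scale 1), which is logged.
    """
    lab = rgb_to_lab(tile.pixels)
    flat = lab.reshape(-1, 3)
    mu = flat.mean(axis=0)
    sigma = flat.std(axis=0)
    scale = np.empty(3)
    for ch in range(3):
        if sigma[ch] < _sigma_floor:
            logger.info(
                "slide %s tile (%d,%d): constant channel %d, shift-only normalization",
                tile.slide_id, tile.row, tile.col, ch,
            )
            scale[ch] = 1.0
        else:
            scale[ch] = ref.std_lab[ch] / sigma[ch]
    out = (lab - mu) * scale + ref.mean_lab
    return Tile(tile.slide_id, tile.row, tile.col, lab_to_rgb(out))


def tile_slide_set(
    manifest: pd.DataFrame,
    out_dir: str | Path,
    ref: ReinhardReference | None = None,
    tile_size: int = DEFAULT_TILE_SIZE,
    white_level: int = DEFAULT_WHITE_LEVEL,
    white_fraction: float = DEFAULT_WHITE_FRACTION,
    normalize: bool = True,
    resolution_um_per_px: float = 0.5,
) -> pd.DataFrame:
    """Tile every slide in the manifest, drop background, normalize, write an index.

    ``manifest`` needs columns ``slide_id`` and ``image_path``.  Kept tiles are
    written as PNG under ``out_dir/<slide_id>/``; the returned index (also
    written to ``out_dir/tiles.csv``) has one row per kept tile plus one
    ``status='failed'`` row per unreadable slide.  Background exclusion runs
    before normalization.  If ``ref`` is None the stats of the first
    non-background tile encountered define the reference, which is saved to
    ``out_dir/reinhard_ref.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[dict] = []
    for _, slide in manifest.iterrows():
        slide_id = str(slide["slide_id"])
        try:
            image = np.asarray(Image.open(slide["image_path"]).convert("RGB"))
        except (OSError, ValueError) as exc:
            logger.warning("slide %s unreadable (%s); skipped", slide_id, exc)
            records.append({"slide_id": slide_id, "row": -1, "col": -1,
                            "path": "", "background": False, "status": "failed"})
            continue
        slide_dir = out_dir / slide_id
        slide_dir.mkdir(exist_ok=True)
        for tile in tile_image(image, tile_size=tile_size, slide_id=slide_id):
            if is_background(tile, white_level=white_level, white_fraction=white_fraction):
                continue
            if ref is None:
                ref = compute_reference(tile)
            if normalize:
                tile = reinhard_normalize(tile, ref)
            path = slide_dir / f"tile_r{tile.row:03d}_c{tile.col:03d}.png"
            Image.fromarray(tile.pixels).save(path)
            records.append({"slide_id": slide_id, "row": tile.row, "col": tile.col,
                            "path": str(path), "background": False, "status": "ok"})
    index = pd.DataFrame(
        records, columns=["slide_id", "row", "col", "path", "background", "status"]
    )
    index.attrs["resolution_um_per_px"] = resolution_um_per_px
    index.to_csv(out_dir / "tiles.csv", index=False)
    if ref is not None:
        ref.to_json(out_dir / "reinhard_ref.json")
    return index
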