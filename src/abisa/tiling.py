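"""Whole-slide tiling with low-information (white-tile) rejection.

A slide is read at its highest-resolution level and cut into non-overlapping
``tile_size`` squares (partial edge tiles are discarded, so the grid is
``floor(H/t) x floor(W/t)``). For each tile, Shannon entropy (bits, over the
256-bin grayscale histogram) and population grayscale variance are computed;
tiles below either threshold are background/glass ("white tiles") and are
discarded. The full grid — kept and discarded — is recorded in a manifest.

Pyramidal TIFFs are read via tifffile (largest series level); plain PNG/TIFF
rasters are accepted as single-level slides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

# ITU-R BT.601 luma weights for grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])

MANIFEST_COLUMNS = [
    "slide_id", "row", "col", "origin_x", "origin_y",
    "entropy_bits", "variance", "kept",
]


@dataclass(frozen=True)
class TileFilterConfig:
    """Tile size and the entropy/variance thresholds of the white-tile filter.

    The thresholds are on 8-bit grayscale: ``entropy_min`` in bits (range
    [0, 8]), ``variance_min`` in squared intensity units. A tile is kept only
    if it meets BOTH thresholds; failing either marks it low-information.
    """

    tile_size: int = 2048
    entropy_min: float = 4.0
    variance_min: float = 100.0

    def __post_init__(self):
        if self.tile_size < 1:
            raise ValueError("tile_size must be >= 1")
        if not 0.0 <= self.entropy_min <= 8.0:
            raise ValueError("entropy_min must be in [0, 8] bits")
        if self.variance_min < 0:
            raise ValueError("variance_min must be >= 0")


@dataclass(frozen=True)
class SlideRef:
    """A slide resolved to one pixel plane (the highest-resolution level)."""

    path: Path
    width_px: int
    height_px: int
    level: int = 0

    def __post_init__(self):
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("slide dimensions must be >= 1")


@dataclass
class Tile:
    row: int
    col: int
    origin_x: int
    origin_y: int
    pixels: np.ndarray
    entropy_bits: float
    variance: float
    kept: bool


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """BT.601 luma of an 8-bit RGB array, rounded to integer bins 0..255."""
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        gray = pixels.astype(np.float64)
    elif pixels.ndim == 3 and pixels.shape[2] >= 3:
        gray = pixels[..., :3].astype(np.float64) @ _LUMA
    else:
        raise ValueError("expected an H x W or H x W x 3 pixel array")
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def shannon_entropy(pixels: np.ndarray) -> float:
    """Shannon entropy in bits of the 256-bin grayscale histogram."""
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("empty pixel array")
    gray = to_grayscale(pixels)
    counts = np.bincount(gray.ravel(), minlength=256)
    p = counts[counts > 0] / gray.size
    return float(-(p * np.log2(p)).sum())


def pixel_variance(pixels: np.ndarray) -> float:
    """Population variance of the grayscale pixel values."""
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("empty pixel array")
    gray = to_grayscale(pixels)
    return float(gray.astype(np.float64).var())


def is_informative(tile: Tile, cfg: TileFilterConfig) -> bool:
    """True iff the tile meets both the entropy and variance thresholds."""
    return tile.entropy_bits >= cfg.entropy_min and tile.variance >= cfg.variance_min


def grid_dimensions(width_px: int, height_px: int, tile_size: int) -> tuple[int, int]:
    """(n_rows, n_cols) of the full-tile grid; partial edge tiles discarded."""
    if width_px < 1 or height_px < 1 or tile_size < 1:
        raise ValueError("width, height and tile_size must all be >= 1")
    return height_px // tile_size, width_px // tile_size


def read_slide(path) -> np.ndarray:
    """Read a slide image as an H x W x 3 uint8 array at the highest level.

    Pyramidal TIFFs expose multiple resolution levels; the largest one is
    selected. PNG and other plain rasters are treated as single-level.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff", ".svs"}:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            series = max(tf.series, key=lambda s: int(np.prod(s.shape)))
            if len(series.levels) > 1:
                level = max(series.levels, key=lambda lv: int(np.prod(lv.shape)))
                arr = level.asarray()
            else:
                arr = series.asarray()
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] > 3:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr.astype(np.uint8, copy=False))


def resolve_slide(path) -> tuple[SlideRef, np.ndarray]:
    arr = read_slide(path)
    ref = SlideRef(path=Path(path), width_px=arr.shape[1], height_px=arr.shape[0])
    return ref, arr


def tile_slide(slide, cfg: TileFilterConfig | None = None,
               slide_id: str | None = None) -> tuple[list[Tile], pd.DataFrame]:
    """Cut a slide into tiles and filter white tiles.

    ``slide`` may be a path, a SlideRef, or an H x W x 3 array. Returns the
    kept tiles in row-major order and a manifest DataFrame listing every
    grid position exactly once with its statistics and kept flag.
    """
    cfg = cfg or TileFilterConfig()
    if isinstance(slide, (str, Path)):
        ref, arr = resolve_slide(slide)
        slide_id = slide_id or Path(slide).stem
    elif isinstance(slide, SlideRef):
        ref, arr = resolve_slide(slide.path)
        slide_id = slide_id or ref.path.stem
    else:
        arr = np.asarray(slide)
        slide_id = slide_id or "slide"

    n_rows, n_cols = grid_dimensions(arr.shape[1], arr.shape[0], cfg.tile_size)
    if n_rows * n_cols == 0:
        logger.warning("slide %s smaller than tile size %d: zero-tile grid",
                       slide_id, cfg.tile_size)
        return [], pd.DataFrame(columns=MANIFEST_COLUMNS)

    kept_tiles: list[Tile] = []
    records = []
    t = cfg.tile_size
    for row in range(n_rows):
        for col in range(n_cols):
            oy, ox = row * t, col * t
            pix = arr[oy:oy + t, ox:ox + t]
            ent = shannon_entropy(pix)
            var = pixel_variance(pix)
            tile = Tile(row=row, col=col, origin_x=ox, origin_y=oy,
                        pixels=pix, entropy_bits=ent, variance=var, kept=False)
            tile.kept = is_informative(tile, cfg)
            if tile.kept:
                kept_tiles.append(tile)
            records.append((slide_id, row, col, ox, oy, ent, var, tile.kept))
    manifest = pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS)
    return kept_tiles, manifest


def write_manifest(manifest: pd.DataFrame, out_dir, slide_id: str,
                   cfg: TileFilterConfig | None = None) -> None:
    """Write the manifest as CSV and JSON (with the filter thresholds logged)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / f"{slide_id}_manifest.csv", index=False)
    payload = {"slide_id": slide_id, "tiles": manifest.to_dict(orient="records")}
    if cfg is not None:
        payload["filter"] = {"tile_size": cfg.tile_size,
                             "entropy_min": cfg.entropy_min,
                             "variance_min": cfg.variance_min}
    import json

    (out_dir / f"{slide_id}_manifest.json").write_text(json.dumps(payload, indent=2))


def write_tiles(tiles: list[Tile], out_dir, slide_id: str) -> list[Path]:
    """Save kept tiles as ``{slide_id}_r{row}_c{col}.png``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tile in tiles:
        p = out_dir / f"{slide_id}_r{tile.row}_c{tile.col}.png"
        Image.fromarray(tile.pixels).save(p)
        paths.append(p)
    return paths
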