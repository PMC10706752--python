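"""Slide-level risk stratification: tile, filter, classify, count, threshold.

A whole slide is called *recurring* when the fraction of its informative
(classified) tiles predicted recurring meets or exceeds a configured
threshold — 15% by default, the value found effective for full-size slides;
smaller slides may warrant a lower threshold, exposed as a per-run override.
The comparison is inclusive and the denominator is all classified tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import resize_tile
from .model import predict_tiles
from .tiling import TileFilterConfig, tile_slide

__all__ = ["AggregationConfig", "SlideDecision", "decide_slide", "classify_slide"]


@dataclass(frozen=True)
class AggregationConfig:
    recurring_fraction_threshold: float = 0.15

    def __post_init__(self):
        if not 0.0 < self.recurring_fraction_threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")


@dataclass
class SlideDecision:
    slide_id: str
    n_tiles_classified: int
    n_recurring_tiles: int
    n_non_recurring_tiles: int
    recurring_fraction: float
    threshold_used: float
    predicted_label: str  # "recurring" | "non_recurring"
    base_resolution: tuple[int, int] | None = None  # (H, W) pixels
    file_size: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


class UndecidableSlideError(RuntimeError):
    """Raised when no informative tile survives filtering."""


def decide_slide(n_recurring: int, n_total: int,
                 cfg: AggregationConfig | None = None,
                 slide_id: str = "slide") -> SlideDecision:
    """Threshold rule on the recurring-tile fraction of one slide."""
    cfg = cfg or AggregationConfig()
    if n_total < 1:
        raise UndecidableSlideError(
            f"slide {slide_id!r} has no classified tiles to aggregate")
    if not 0 <= n_recurring <= n_total:
        raise ValueError("n_recurring must lie in [0, n_total]")
    fraction = n_recurring / n_total
    label = ("recurring" if fraction >= cfg.recurring_fraction_threshold
             else "non_recurring")
    return SlideDecision(
        slide_id=slide_id,
        n_tiles_classified=n_total,
        n_recurring_tiles=n_recurring,
        n_non_recurring_tiles=n_total - n_recurring,
        recurring_fraction=fraction,
        threshold_used=cfg.recurring_fraction_threshold,
        predicted_label=label,
    )


def classify_slide(slide, model, filter_cfg: TileFilterConfig | None = None,
                   agg_cfg: AggregationConfig | None = None,
                   slide_id: str | None = None,
                   ) -> tuple[SlideDecision, pd.DataFrame]:
    """End-to-end call on one slide.

    ``slide`` is a path or an H x W x 3 array; ``model`` is anything with the
    tile classifier's ``predict_proba``/``config`` surface (a ground-truth
    stand-in works for pipeline tests). Returns the decision plus a per-tile
    manifest extended with predicted label and recurring probability.
    """
    filter_cfg = filter_cfg or TileFilterConfig()
    agg_cfg = agg_cfg or AggregationConfig()
    if slide_id is None:
        slide_id = Path(slide).stem if isinstance(slide, (str, Path)) else "slide"

    kept, manifest = tile_slide(slide, filter_cfg, slide_id=slide_id)
    if not kept:
        raise UndecidableSlideError(
            f"slide {slide_id!r}: no informative tiles after filtering")

    target = model.config.image_size
    batch = np.stack([resize_tile(t.pixels, target) for t in kept])
    probs, labels = predict_tiles(model, batch)

    manifest = manifest.copy()
    manifest["pred_label"] = pd.array([None] * len(manifest), dtype=object)
    manifest["p_recurring"] = np.nan
    kept_pos = manifest.index[manifest["kept"]]
    manifest.loc[kept_pos, "pred_label"] = np.where(labels == 1, "recurring",
                                                    "non_recurring")
    manifest.loc[kept_pos, "p_recurring"] = probs[:, 1]

    n_rec = int((labels == 1).sum())
    decision = decide_slide(n_rec, len(kept), agg_cfg, slide_id=slide_id)
    if isinstance(slide, (str, Path)):
        p = Path(slide)
        decision.file_size = p.stat().st_size
    arr_shape = None
    if isinstance(slide, np.ndarray):
        arr_shape = slide.shape[:2]
    else:
        h = manifest["origin_y"].max() + filter_cfg.tile_size
        w = manifest["origin_x"].max() + filter_cfg.tile_size
        arr_shape = (int(h), int(w))
    decision.base_resolution = tuple(arr_shape)
    return decision, manifest
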