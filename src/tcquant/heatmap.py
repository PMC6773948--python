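"""Whole-slide tiling over a tumour-bed polygon and heatmap rendering.

A slide (here a flat mosaic image; pyramidal WSI decoding is an adapter
concern outside the core path) is tiled into half-open square windows. A
window belongs to the tumour bed iff its centre lies strictly inside the
annotated polygon — a cheap rule that avoids double-counting boundary
patches. Each window is scored by any patch scorer and the grid is rendered
as a colour overlay where 0% TC maps to pure blue and 100% TC to pure red.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap
from PIL import Image
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

#: Linear blue -> red map: 0 is pure blue, 100 pure red, 50 the midpoint.
TC_COLORMAP = LinearSegmentedColormap.from_list(
    "tc_blue_red", [(0.0, 0.0, 1.0), (1.0, 0.0, 0.0)]
)

UNSCORED = np.nan


def tile_tumour_bed(
    slide_dims: tuple[int, int],
    polygon,
    patch_size_px: int,
    stride_px: int,
) -> list[tuple[int, int]]:
    """Window origins (x, y) whose centres fall inside the tumour bed.

    ``slide_dims`` is (width, height) in pixels. Windows are half-open
    [x, x+size) x [y, y+size); windows that would cross the slide boundary
    are excluded rather than clipped. Returns origins in row-major order.
    An annotation lying entirely outside the slide yields an empty list
    with a warning.
    """
    width, height = slide_dims
    if stride_px < 1:
        raise ValueError("stride must be >= 1")
    if patch_size_px < 1:
        raise ValueError("patch size must be >= 1")
    poly = Polygon(np.asarray(polygon, float))
    if not (poly.is_valid and poly.is_simple):
        raise ValueError("tumour-bed polygon must be simple")

    windows: list[tuple[int, int]] = []
    half = patch_size_px / 2.0
    for y in range(0, height - patch_size_px + 1, stride_px):
        for x in range(0, width - patch_size_px + 1, stride_px):
            if poly.contains(Point(x + half, y + half)):
                windows.append((x, y))
    if not windows:
        minx, miny, maxx, maxy = poly.bounds
        if maxx < 0 or maxy < 0 or minx > width or miny > height:
            warnings.warn("tumour-bed polygon lies outside the slide", stacklevel=2)
    return windows


@dataclass
class SlideScoreGrid:
    """Per-window scores over a slide: a table with columns
    ``x, y, score, stage`` (score is NaN for unscored windows)."""

    table: pd.DataFrame
    patch_size_px: int
    method: str = "unknown"

    def __post_init__(self):
        coords = list(zip(self.table["x"], self.table["y"]))
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate window origins in score grid")
        scored = self.table["score"].dropna()
        if len(scored) and (scored.min() < 0 or scored.max() > 100):
            raise ValueError("scores must lie in [0, 100]")


def score_slide(
    scorer,
    slide_image: np.ndarray,
    windows: list[tuple[int, int]],
    patch_size_px: int,
    method: str = "unknown",
) -> SlideScoreGrid:
    """Score every window with ``scorer(patch) -> float | TCScore |
    CascadePrediction``.

    Window order does not affect the result. A scorer failure on one
    window marks it unscored (NaN), logs the error, and the run continues.
    """
    rows = []
    for x, y in sorted(windows, key=lambda w: (w[1], w[0])):
        patch = slide_image[y : y + patch_size_px, x : x + patch_size_px]
        stage = ""
        try:
            result = scorer(patch)
            if hasattr(result, "tc_value"):  # CascadePrediction
                score, stage = float(result.tc_value), result.stage
            elif hasattr(result, "value"):  # TCScore
                score, stage = float(result.value), result.method
            else:
                score = float(result)
        except Exception as e:  # noqa: BLE001 - per-window fault isolation
            logger.error("scorer failed on window (%d, %d): %s", x, y, e)
            score, stage = UNSCORED, "error"
        rows.append({"x": x, "y": y, "score": score, "stage": stage})
    table = pd.DataFrame(rows, columns=["x", "y", "score", "stage"])
    return SlideScoreGrid(table=table, patch_size_px=patch_size_px, method=method)


def render_heatmap(
    grid: SlideScoreGrid,
    slide_image: np.ndarray,
    colormap=TC_COLORMAP,
    alpha: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Blend per-window score colours onto the slide.

    Returns ``(overlay, legend)`` uint8 RGB arrays. The tint colour is a
    linear interpolation along the colormap with 0 -> blue endpoint and
    100 -> red endpoint; unscored windows stay untinted. Deterministic for
    fixed inputs.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    overlay = np.asarray(slide_image, float).copy()
    size = grid.patch_size_px
    for row in grid.table.itertuples(index=False):
        if np.isnan(row.score):
            continue
        colour = 255.0 * np.asarray(colormap(row.score / 100.0)[:3])
        window = overlay[row.y : row.y + size, row.x : row.x + size]
        window[:] = (1.0 - alpha) * window + alpha * colour
    overlay = np.clip(np.round(overlay), 0, 255).astype(np.uint8)

    ramp = np.linspace(0.0, 1.0, 256)
    legend = np.tile(
        (255.0 * np.asarray([colormap(v)[:3] for v in ramp]))[None, :, :], (20, 1, 1)
    )
    legend = np.clip(np.round(legend), 0, 255).astype(np.uint8)
    return overlay, legend


def save_png(image: np.ndarray, path) -> None:
    """Write an 8-bit PNG with deterministic bytes."""
    Image.fromarray(image).save(path, format="PNG")
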