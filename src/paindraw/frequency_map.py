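"""The probe tool: per-pixel pain-report frequency across a cohort.

Accumulating the paint masks of a group of drawings gives, for every body
pixel, the number of individuals who reported pain there.  Rendered as a
color grid over the reference image, this shows the cohort's most common
pain locations; the scalar summary ``max_count/n_images`` (the deepest
overlap anywhere on the body over the subset size) goes into the report
footer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .errors import EmptyCohortError, InputError
from .drawing_analysis import PaintMask
from .reference_map import BodyMask, ReferenceImage

DEFAULT_CELL_PX = 8
DEFAULT_COLORMAP = "viridis"


@dataclass
class FrequencyMap:
    """Integer raster of per-pixel report counts over ``n_images`` drawings."""

    counts: np.ndarray
    n_images: int


def accumulate(paints: list[PaintMask], mask: BodyMask) -> FrequencyMap:
    """Count, per pixel, how many paint masks cover it.

    All masks must share the body mask's dimensions and be clipped to the
    body (counts outside the body are forced to zero).
    """
    if not paints:
        raise EmptyCohortError("cannot accumulate zero paint masks")
    counts = np.zeros(mask.body.shape, dtype=np.int32)
    for paint in paints:
        if paint.painted.shape != mask.body.shape:
            raise InputError(
                f"paint mask shape {paint.painted.shape} does not match "
                f"body mask shape {mask.body.shape}"
            )
        counts += paint.painted
    counts[~mask.body] = 0
    return FrequencyMap(counts=counts, n_images=len(paints))


def freq_summary(freq: FrequencyMap, subset_size: int) -> tuple[int, int]:
    """``(max per-pixel count, subset size)`` — printed as ``m/n``."""
    if subset_size != freq.n_images:
        raise InputError(
            f"subset_size {subset_size} does not match the map's "
            f"n_images {freq.n_images}"
        )
    return int(freq.counts.max()), subset_size


def render_probe(
    freq: FrequencyMap,
    mask: BodyMask,
    ref: ReferenceImage,
    cell_px: int = DEFAULT_CELL_PX,
    colormap_name: str = DEFAULT_COLORMAP,
) -> np.ndarray:
    """Render the frequency map as a color grid over the reference.

    The raster is tiled into ``cell_px`` x ``cell_px`` cells; each cell's
    in-body pixels are colored by mapping the cell's mean count divided by
    ``n_images`` through the named colormap.  Out-of-body pixels keep the
    reference rendering.
    """
    if cell_px < 1:
        raise InputError(f"cell_px must be >= 1, got {cell_px}")
    cmap = colormaps[colormap_name]
    h, w = freq.counts.shape
    out = ref.pixels.copy()
    denom = max(freq.n_images, 1)
    for y0 in range(0, h, cell_px):
        for x0 in range(0, w, cell_px):
            cell_body = mask.body[y0:y0 + cell_px, x0:x0 + cell_px]
            if not cell_body.any():
                continue
            cell_counts = freq.counts[y0:y0 + cell_px, x0:x0 + cell_px]
            value = cell_counts[cell_body].mean() / denom
            rgb = (np.asarray(cmap(float(value))[:3]) * 255).round()
            out[y0:y0 + cell_px, x0:x0 + cell_px][cell_body] = (
                rgb.astype(np.uint8)
            )
    return out
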