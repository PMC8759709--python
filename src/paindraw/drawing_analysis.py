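"""Per-drawing pain-extent analysis.

A patient drawing is the reference image with chromatic stylus strokes on
top.  Pain extent is the fraction of body pixels the patient colored:

    ratio (%) = 100 * painted_in_body_pixels / total_body_pixels

Detection is purely per-pixel, so stroke type and size do not influence the
result — only the set of covered pixels does.  A pixel counts as painted
iff it differs from the reference at that position *and* is chromatic; any
pen color works except black and white, which are reserved for the
template.  Strokes outside the body outline are clipped away, and the
optional "smart" pass fills fully enclosed uncolored gaps the patient
evidently meant to cover.  For visual verification, counted pixels are
repainted in the channel-wise complement of the pen color.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateReferenceError, InputError
from .reference_map import FOUR_CONNECTED, BodyMask, ReferenceImage, load_reference

DEFAULT_SATURATION_MIN = 0.15
DEFAULT_VALUE_WINDOW = 30
DEFAULT_NEAR_BLACK_MAX = 40
DEFAULT_NEAR_WHITE_MIN = 215


@dataclass
class PaintMask:
    """The set of counted (patient-colored) pixels of one drawing.

    ``pen_color`` is the modal RGB triple over the painted pixels, or
    ``None`` when nothing is painted.
    """

    painted: np.ndarray
    pen_color: tuple[int, int, int] | None
    painted_pixels: int


@dataclass
class AnalysisResult:
    """One drawing's pain-extent measurement (one row of the report)."""

    filename: str
    painted_pixels: int
    total_body_pixels: int
    ratio_percent: float
    cs_flag: bool | None = None
    overlay: np.ndarray | None = None


def _modal_color(pixels: np.ndarray) -> tuple[int, int, int]:
    """Most frequent RGB triple in an (N, 3) uint8 array (ties: smallest)."""
    packed = (
        pixels[:, 0].astype(np.int64) << 16
    ) | (pixels[:, 1].astype(np.int64) << 8) | pixels[:, 2].astype(np.int64)
    values, counts = np.unique(packed, return_counts=True)
    mode = int(values[np.argmax(counts)])
    return (mode >> 16 & 255, mode >> 8 & 255, mode & 255)


def detect_painted_pixels(
    drawing: ReferenceImage,
    ref: ReferenceImage,
    saturation_min: float = DEFAULT_SATURATION_MIN,
    value_window: int = DEFAULT_VALUE_WINDOW,
    near_black_max: int = DEFAULT_NEAR_BLACK_MAX,
    near_white_min: int = DEFAULT_NEAR_WHITE_MIN,
) -> PaintMask:
    """Find the pixels the patient colored.

    A pixel is painted iff it differs from the reference pixel at the same
    position and is chromatic: channel spread ``max - min`` above
    ``value_window`` or HSV saturation above ``saturation_min``.  Near-black
    (max channel < ``near_black_max``) and near-white (min channel >
    ``near_white_min``) pixels never count, since black and white are the
    template's own colors.  Requiring a difference from the reference keeps
    app-side antialiasing of strokes over black outlines from counting
    spuriously.

    Zero painted pixels is a valid outcome (ratio 0), not an error.

    Raises
    ------
    InputError
        If drawing and reference dimensions differ.
    """
    if drawing.pixels.shape != ref.pixels.shape:
        raise InputError(
            f"drawing size {drawing.width}x{drawing.height} does not match "
            f"reference size {ref.width}x{ref.height}"
        )
    px = drawing.pixels.astype(np.int16)
    differs = (drawing.pixels != ref.pixels).any(axis=2)
    mx = px.max(axis=2)
    mn = px.min(axis=2)
    spread = mx - mn
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(mx > 0, spread / np.maximum(mx, 1), 0.0)
    chromatic = (spread > value_window) | (saturation > saturation_min)
    near_black = mx < near_black_max
    near_white = mn > near_white_min
    painted = differs & chromatic & ~near_black & ~near_white
    n = int(painted.sum())
    pen = _modal_color(drawing.pixels[painted]) if n else None
    return PaintMask(painted=painted, pen_color=pen, painted_pixels=n)


def clip_to_body(paint: PaintMask, mask: BodyMask) -> PaintMask:
    """Discard painted pixels outside the body outline."""
    if paint.painted.shape != mask.body.shape:
        raise InputError(
            f"paint mask shape {paint.painted.shape} does not match body "
            f"mask shape {mask.body.shape}"
        )
    clipped = paint.painted & mask.body
    return PaintMask(
        painted=clipped,
        pen_color=paint.pen_color,
        painted_pixels=int(clipped.sum()),
    )


def smart_fill(paint: PaintMask, mask: BodyMask) -> PaintMask:
    """Fill uncolored gaps fully enclosed by painted strokes.

    Every 4-connected unpainted region of the raster that does not touch
    the image border is added to the painted set (standard binary hole
    filling), and the result is re-clipped to the body.  The operation is
    monotone and idempotent; open gaps that connect to the border-reachable
    unpainted region are left alone.
    """
    filled = ndimage.binary_fill_holes(paint.painted, structure=FOUR_CONNECTED)
    filled &= mask.body
    return PaintMask(
        painted=filled,
        pen_color=paint.pen_color,
        painted_pixels=int(filled.sum()),
    )


def pain_extent(paint: PaintMask, mask: BodyMask) -> float:
    """Painted body fraction as a percentage, at full precision.

    Rounding happens only at report export.
    """
    if mask.total_body_pixels == 0:
        raise DegenerateReferenceError("body mask has zero pixels")
    return 100.0 * paint.painted_pixels / mask.total_body_pixels


def complementary_overlay(drawing: ReferenceImage, paint: PaintMask) -> np.ndarray:
    """Repaint counted pixels with the complement of the pen color.

    Output equals the drawing except that every counted pixel is set to
    ``(255-R, 255-G, 255-B)`` of the pen color, making the area that took
    part in the calculation visually verifiable.  An empty paint mask
    returns the drawing unchanged.
    """
    overlay = drawing.pixels.copy()
    if paint.painted_pixels > 0 and paint.pen_color is not None:
        complement = np.array(
            [255 - c for c in paint.pen_color], dtype=np.uint8
        )
        overlay[paint.painted] = complement
    return overlay


def analyze_drawing(
    path,
    ref: ReferenceImage,
    mask: BodyMask,
    smart: bool = False,
    saturation_min: float = DEFAULT_SATURATION_MIN,
    value_window: int = DEFAULT_VALUE_WINDOW,
    near_black_max: int = DEFAULT_NEAR_BLACK_MAX,
    near_white_min: int = DEFAULT_NEAR_WHITE_MIN,
) -> tuple[AnalysisResult, PaintMask]:
    """Run the full per-drawing pipeline on an image file.

    detect -> clip to body -> (smart fill) -> pain extent -> overlay.
    Returns the result row together with the final paint mask (which
    cohort-level tools such as the probe accumulate).
    """
    drawing = load_reference(path)
    paint = detect_painted_pixels(
        drawing, ref,
        saturation_min=saturation_min, value_window=value_window,
        near_black_max=near_black_max, near_white_min=near_white_min,
    )
    paint = clip_to_body(paint, mask)
    if smart:
        paint = smart_fill(paint, mask)
    ratio = pain_extent(paint, mask)
    overlay = complementary_overlay(drawing, paint)
    result = AnalysisResult(
        filename=os.path.basename(os.fspath(path)),
        painted_pixels=paint.painted_pixels,
        total_body_pixels=mask.total_body_pixels,
        ratio_percent=ratio,
        overlay=overlay,
    )
    return result, paint
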