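"""Synthetic references and simulated patient drawings with known truth.

Nothing here tries to be anatomically pretty: the point is a fully
controlled stand-in for the real artwork and real patients, so that every
pipeline stage can be checked against exact ground truth without any
external file.  The generated reference mimics the real template's
load-bearing properties: a white field, two genderless figures built from
rectangles and an elliptical head, closed 1-px black outlines with no
antialiasing (only pure black and pure white pixels), and a right figure
that is the exact horizontal mirror of the left one — so the front and
back body areas have exactly the same pixel count by construction.

Simulated drawings paint an exact, known number of in-body pixels by
seeded region growing (connected, stroke-like blobs), optionally adding
out-of-body leak pixels (which clipping must remove) and enclosed
unpainted holes (which the smart fill must recover).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .cohort_stats import CohortReport, summarize
from .drawing_analysis import (
    DEFAULT_NEAR_BLACK_MAX,
    DEFAULT_NEAR_WHITE_MIN,
    DEFAULT_SATURATION_MIN,
    DEFAULT_VALUE_WINDOW,
    AnalysisResult,
    PaintMask,
)
from .reference_map import BodyMask, ReferenceImage

DEFAULT_PEN_COLOR = (220, 30, 30)

#: Approximate body-surface shares of the generated regions, in the spirit
#: of the Rule of Nines burn chart (head ~9%, each arm ~9%, each leg ~18%,
#: trunk ~36%).  Metadata about the artwork's proportions, not an enforced
#: constraint.
RULE_OF_NINES_GUIDE = {
    "head": 0.09, "arm": 0.09, "leg": 0.18, "trunk": 0.36,
}

_NEIGHBORS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class SyntheticSpec:
    """Parameters of one simulated drawing.

    ``target_fraction`` is realized as an exact integer pixel count of the
    hole-filled painted region; ``hole_spec`` rectangles are ``(x, y, w,
    h)`` boxes that end up unpainted but fully enclosed by paint.
    """

    width: int
    height: int
    target_fraction: float
    pen_color: tuple[int, int, int] = DEFAULT_PEN_COLOR
    leak_pixels: int = 0
    hole_spec: list[tuple[int, int, int, int]] = field(default_factory=list)
    seed: int = 0


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _silhouette(half_w: int, height: int, rng: np.random.Generator):
    """Filled boolean silhouette of one figure on a half-width canvas."""
    m = 4  # margin keeps figures off the border and off the midline
    fh = height - 2 * m
    cx = half_w / 2
    # small seeded jitter so different seeds give distinct (but equally
    # valid) artwork
    jx = int(rng.integers(-2, 3))
    jy = int(rng.integers(-2, 3))
    cx += jx

    shape = np.zeros((height, half_w), dtype=bool)
    # head
    head_cy = m + 0.10 * fh + jy
    shape |= _ellipse(height, half_w, head_cy, cx, 0.085 * fh, 0.11 * half_w)
    # neck (guarantees 4-connectivity head-torso)
    y0, y1 = int(head_cy), int(m + 0.20 * fh)
    x0, x1 = int(cx - 0.03 * half_w), int(cx + 0.03 * half_w) + 1
    shape[y0:y1, x0:x1] = True
    # trunk
    ty0, ty1 = int(m + 0.18 * fh), int(m + 0.55 * fh)
    shape[ty0:ty1, int(cx - 0.18 * half_w):int(cx + 0.18 * half_w) + 1] = True
    # arms
    ay1 = int(m + 0.50 * fh)
    shape[ty0:ay1, int(cx - 0.34 * half_w):int(cx - 0.18 * half_w)] = True
    shape[ty0:ay1, int(cx + 0.18 * half_w) + 1:int(cx + 0.34 * half_w)] = True
    # legs
    ly1 = int(m + 0.95 * fh)
    shape[ty1:ly1, int(cx - 0.16 * half_w):int(cx - 0.03 * half_w)] = True
    shape[ty1:ly1, int(cx + 0.03 * half_w) + 1:int(cx + 0.16 * half_w)] = True
    # clip to the margin box so mirrored figures never touch the midline
    box = np.zeros_like(shape)
    box[m:height - m, m:half_w - m] = True
    return shape & box


def _outline(shape: np.ndarray) -> np.ndarray:
    """Silhouette pixels with a 4-neighbor (or the border) outside."""
    padded = np.pad(shape, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1]
        & padded[1:-1, :-2] & padded[1:-1, 2:]
        & shape
    )
    return shape & ~interior


def generate_reference(
    width: int, height: int, seed: int = 0
) -> tuple[ReferenceImage, BodyMask]:
    """Generate a two-figure reference image plus its ground-truth mask.

    The right figure is the pixel-exact mirror of the left one, so
    ``front`` and ``back`` counts are equal by construction.  Only pure
    black (outline) and pure white pixels are emitted.

    Raises
    ------
    ParameterError
        If the canvas is smaller than 64x64.
    """
    if width < 64 or height < 64:
        raise ParameterError(
            f"canvas {width}x{height} too small for silhouettes "
            "(need >= 64x64)"
        )
    rng = np.random.default_rng(seed)
    half_w = width // 2
    left = _silhouette(half_w, height, rng)
    if not left.any():
        raise ParameterError("silhouette construction produced no pixels")
    body = np.zeros((height, width), dtype=bool)
    body[:, :half_w] = left
    body[:, width - half_w:] = left[:, ::-1]

    pixels = np.full((height, width, 3), 255, dtype=np.uint8)
    pixels[_outline(body)] = 0

    front = body.copy()
    front[:, half_w:] = False
    back = body & ~front
    mask = BodyMask(body=body, front=front, back=back,
                    total_body_pixels=int(body.sum()))
    return ReferenceImage(pixels), mask


def _grow_region(
    body: np.ndarray, k: int, start: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Breadth-first region of exactly ``k`` body pixels, reseeding into
    other body components when one is exhausted."""
    h, w = body.shape
    region = np.zeros_like(body)
    queue: deque[tuple[int, int]] = deque([start])
    grown = 0
    while grown < k:
        if not queue:
            remaining = np.argwhere(body & ~region)
            pick = remaining[int(rng.integers(len(remaining)))]
            queue.append((int(pick[0]), int(pick[1])))
        y, x = queue.popleft()
        if region[y, x] or not body[y, x]:
            continue
        region[y, x] = True
        grown += 1
        for dy, dx in _NEIGHBORS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and body[ny, nx] \
                    and not region[ny, nx]:
                queue.append((ny, nx))
    return region


def _leak_region(body: np.ndarray, k: int) -> np.ndarray:
    """First ``k`` background pixels reachable from the top-left corner."""
    h, w = body.shape
    region = np.zeros_like(body)
    queue: deque[tuple[int, int]] = deque([(0, 0)])
    grown = 0
    while grown < k and queue:
        y, x = queue.popleft()
        if region[y, x] or body[y, x]:
            continue
        region[y, x] = True
        grown += 1
        for dy, dx in _NEIGHBORS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not body[ny, nx] \
                    and not region[ny, nx]:
                queue.append((ny, nx))
    if grown < k:
        raise ParameterError(
            f"cannot place {k} leak pixels: only {grown} background pixels "
            "reachable from the corner"
        )
    return region


def _check_pen_detectable(pen: tuple[int, int, int]) -> None:
    r, g, b = pen
    mx, mn = max(pen), min(pen)
    spread = mx - mn
    sat = spread / mx if mx else 0.0
    chromatic = spread > DEFAULT_VALUE_WINDOW or sat > DEFAULT_SATURATION_MIN
    if not chromatic or mx < DEFAULT_NEAR_BLACK_MAX \
            or mn > DEFAULT_NEAR_WHITE_MIN:
        raise ParameterError(
            f"pen color {pen} would be rejected by the default chromatic "
            "pen detection (black/white and achromatic tones are reserved)"
        )


def simulate_drawing(
    ref: ReferenceImage, mask: BodyMask, spec: SyntheticSpec
) -> tuple[ReferenceImage, PaintMask]:
    """Paint a simulated patient drawing over the reference.

    Exactly ``round(target_fraction * total_body_pixels)`` in-body pixels
    form the intended (hole-filled) painted region, grown breadth-first
    from a seeded pixel.  ``leak_pixels`` additional pen pixels are placed
    outside the body, and each ``hole_spec`` rectangle is carved back to
    the reference rendering (unpainted, but fully enclosed by paint).

    Returns the drawing and the ground-truth intended paint mask (in-body,
    hole-filled).
    """
    if spec.width != ref.width or spec.height != ref.height:
        raise ParameterError(
            f"spec canvas {spec.width}x{spec.height} does not match "
            f"reference {ref.width}x{ref.height}"
        )
    if not 0.0 <= spec.target_fraction <= 1.0:
        raise ParameterError(
            f"target_fraction must be in [0, 1], got {spec.target_fraction}"
        )
    _check_pen_detectable(spec.pen_color)
    rng = np.random.default_rng(spec.seed)
    k = int(round(spec.target_fraction * mask.total_body_pixels))

    region = np.zeros_like(mask.body)
    if k > 0:
        if spec.hole_spec:
            x, y, w, h = spec.hole_spec[0]
            start = (y + h // 2, x + w // 2)
            if not mask.body[start]:
                raise ParameterError(
                    f"hole at {spec.hole_spec[0]} is not centered on a "
                    "body pixel"
                )
        else:
            candidates = np.argwhere(mask.body)
            pick = candidates[int(rng.integers(len(candidates)))]
            start = (int(pick[0]), int(pick[1]))
        region = _grow_region(mask.body, k, start, rng)

    drawing = ref.pixels.copy()
    pen = np.array(spec.pen_color, dtype=np.uint8)
    drawing[region] = pen

    # enclosed holes: carve back to the reference, demand a painted ring
    holes = np.zeros_like(mask.body)
    for x, y, w, h in spec.hole_spec:
        if w < 1 or h < 1 or x < 1 or y < 1 \
                or x + w >= ref.width or y + h >= ref.height:
            raise ParameterError(f"degenerate hole box {(x, y, w, h)}")
        box = np.zeros_like(mask.body)
        box[y:y + h, x:x + w] = True
        ring = np.zeros_like(mask.body)
        ring[y - 1:y + h + 1, x - 1:x + w + 1] = True
        ring &= ~box
        if not region[box].all() or not region[ring].all():
            raise ParameterError(
                f"hole {(x, y, w, h)} is not strictly inside the painted "
                "region (cannot be enclosed)"
            )
        holes |= box
    drawing[holes] = ref.pixels[holes]

    if spec.leak_pixels:
        leak = _leak_region(mask.body, spec.leak_pixels)
        drawing[leak] = pen

    truth = PaintMask(
        painted=region, pen_color=spec.pen_color, painted_pixels=k,
    )
    return ReferenceImage(drawing), truth


def stratified_fraction_sampler(
    n_low: int,
    n_high: int,
    low_range: tuple[float, float] = (0.03, 0.14),
    high_range: tuple[float, float] = (0.19, 0.40),
    seed: int = 0,
):
    """Sampler producing exactly ``n_high`` fractions in ``high_range`` and
    ``n_low`` in ``low_range``, in seeded shuffled order.

    Useful for simulating a cohort with a prescribed number of
    above-threshold (CS) drawings: keep the ranges clear of the threshold
    so pixel quantization cannot flip a classification.  The returned
    callable matches the ``fraction_sampler(rng)`` interface of
    :func:`simulate_cohort` (the argument is ignored; the sequence is
    fixed at construction) and raises :class:`ParameterError` when drawn
    more than ``n_low + n_high`` times.
    """
    rng = np.random.default_rng(seed)
    fractions = np.concatenate([
        rng.uniform(*low_range, size=n_low),
        rng.uniform(*high_range, size=n_high),
    ])
    rng.shuffle(fractions)
    it = iter(fractions.tolist())

    def sampler(_rng) -> float:
        try:
            return next(it)
        except StopIteration:
            raise ParameterError(
                f"sampler exhausted after {n_low + n_high} draws"
            ) from None

    return sampler


def simulate_cohort(
    ref: ReferenceImage,
    mask: BodyMask,
    n: int,
    fraction_sampler,
    threshold: float,
    seed: int = 0,
) -> tuple[list[tuple[str, ReferenceImage, PaintMask]], CohortReport]:
    """Simulate ``n`` drawings and the ground-truth cohort report.

    ``fraction_sampler(rng)`` draws each drawing's target fraction.  The
    returned report is computed from the exact realized ratios (fractions
    quantized to whole pixels), so a correct pipeline reproduces it to
    full precision.
    """
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    drawings: list[tuple[str, ReferenceImage, PaintMask]] = []
    truth_results: list[AnalysisResult] = []
    for i in range(1, n + 1):
        fraction = float(fraction_sampler(rng))
        spec = SyntheticSpec(
            width=ref.width, height=ref.height, target_fraction=fraction,
            seed=int(rng.integers(2**31)),
        )
        drawing, truth = simulate_drawing(ref, mask, spec)
        name = f"Name {i}.png"
        drawings.append((name, drawing, truth))
        truth_results.append(AnalysisResult(
            filename=name,
            painted_pixels=truth.painted_pixels,
            total_body_pixels=mask.total_body_pixels,
            ratio_percent=100.0 * truth.painted_pixels
            / mask.total_body_pixels,
        ))
    report = summarize(truth_results, threshold)
    return drawings, report
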