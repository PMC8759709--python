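"""Reference body-map handling.

The analysis is anchored on a reference image (RI): a standardized body
outline — black, non-antialiased strokes on a white field, typically two
figures (front and back view) side by side.  This module loads such an
image, derives the *body mask* (every pixel belonging to a body silhouette,
outline included), and splits the mask into the front and back figures.

The body mask is found by flood-filling the near-white background inward
from the image border: any pixel that cannot be reached that way — outline
pixels and everything they enclose — is body.  Because the strokes are
drawn without antialiasing, a small per-channel gray tolerance suffices to
absorb residual gray tones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import DegenerateReferenceError, InputError

logger = logging.getLogger(__name__)

#: 4-connected structuring element (von Neumann neighborhood).  Background
#: flood fill uses 4-connectivity so it cannot leak through diagonal gaps
#: in 1-px outlines.
FOUR_CONNECTED = ndimage.generate_binary_structure(2, 1)

DEFAULT_GRAY_TOLERANCE = 10


@dataclass(frozen=True)
class ReferenceImage:
    """An RGB raster with the alpha channel (if any) composited over white.

    Attributes
    ----------
    pixels : numpy.ndarray
        ``(height, width, 3)`` uint8 array of RGB triples.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise InputError(
                f"expected an (H, W, 3) uint8 raster, got shape {px.shape} "
                f"dtype {px.dtype}"
            )
        if px.shape[1] < 2 or px.shape[0] < 1:
            raise InputError(
                f"raster too small: {px.shape[1]}x{px.shape[0]} "
                "(need width >= 2, height >= 1)"
            )

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class BodyMask:
    """Boolean rasters delimiting the body area of a reference image.

    ``front`` and ``back`` are disjoint and their union is ``body``;
    ``total_body_pixels`` is the whole-body denominator of every pain-extent
    ratio.
    """

    body: np.ndarray
    front: np.ndarray
    back: np.ndarray
    total_body_pixels: int


def load_reference(path) -> ReferenceImage:
    """Load a raster image as a :class:`ReferenceImage`.

    Any format the image reader decodes is accepted; RGBA input is
    composited over a white background before the alpha channel is dropped.

    Raises
    ------
    InputError
        If the file cannot be read or decoded.
    """
    try:
        with Image.open(path) as img:
            img.load()
            rgba = img.convert("RGBA")
    except Exception as exc:  # Pillow raises many concrete types
        raise InputError(f"cannot read image {path!s}: {exc}") from exc
    background = Image.new("RGBA", rgba.size, (255, 255, 255, 255))
    composited = Image.alpha_composite(background, rgba).convert("RGB")
    return ReferenceImage(np.asarray(composited, dtype=np.uint8))


def build_body_mask(
    ref: ReferenceImage, gray_tolerance: int = DEFAULT_GRAY_TOLERANCE
) -> BodyMask:
    """Derive the body mask from a reference image.

    Background is defined as the set of near-white pixels (every channel
    >= ``255 - gray_tolerance``) 4-connected to the image border; body is
    its complement.  Outline pixels and any white pixels fully enclosed by
    the outline are therefore body, so the measured area is the whole
    silhouette, independent of stroke thickness.

    The returned mask has ``front``/``back`` unpopulated (all False); call
    :func:`split_front_back` to fill them in.

    Raises
    ------
    DegenerateReferenceError
        If no body pixel is found (e.g. an all-white image).
    """
    near_white = (ref.pixels >= 255 - gray_tolerance).all(axis=2)
    labels, _ = ndimage.label(near_white, structure=FOUR_CONNECTED)
    border_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border_labels = border_labels[border_labels != 0]
    background = np.isin(labels, border_labels)
    body = ~background
    total = int(body.sum())
    if total == 0:
        raise DegenerateReferenceError(
            "reference image has no body pixels (everything is background)"
        )
    empty = np.zeros_like(body)
    return BodyMask(body=body, front=empty.copy(), back=empty.copy(),
                    total_body_pixels=total)


def split_front_back(
    mask: BodyMask, ref: ReferenceImage, split_x: float | None = None
) -> BodyMask:
    """Assign each connected body figure to the front or back half.

    The reference artwork places the front-view figure left of the
    back-view figure; each 4-connected component of the body goes to
    ``front`` if its centroid lies left of ``split_x`` (default: the image
    midline), else to ``back``.  A single centered figure degenerates to
    all-front with a logged warning.
    """
    if split_x is None:
        split_x = ref.width / 2
    labels, n = ndimage.label(mask.body, structure=FOUR_CONNECTED)
    front = np.zeros_like(mask.body)
    back = np.zeros_like(mask.body)
    if n:
        centroids = ndimage.center_of_mass(mask.body, labels, range(1, n + 1))
        for lab, (_, cx) in enumerate(centroids, start=1):
            target = front if cx < split_x else back
            target |= labels == lab
    if not back.any() or not front.any():
        logger.warning(
            "front/back split is degenerate: no component fell on the %s "
            "side of x=%.1f", "back" if not back.any() else "front", split_x,
        )
    return BodyMask(body=mask.body, front=front, back=back,
                    total_body_pixels=mask.total_body_pixels)


def prepare_reference(
    path, gray_tolerance: int = DEFAULT_GRAY_TOLERANCE,
    split_x: float | None = None,
) -> tuple[ReferenceImage, BodyMask]:
    """Convenience: load the reference, build its mask and split it."""
    ref = load_reference(path)
    mask = build_body_mask(ref, gray_tolerance=gray_tolerance)
    mask = split_front_back(mask, ref, split_x=split_x)
    logger.info(
        "reference %s: %dx%d, body=%d px (front=%d, back=%d), "
        "gray_tolerance=%d", path, ref.width, ref.height,
        mask.total_body_pixels, int(mask.front.sum()), int(mask.back.sum()),
        gray_tolerance,
    )
    return ref, mask
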