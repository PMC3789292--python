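"""Display-preparation operators: negative, brightness/contrast, distance.

These mirror the tools a radiologist uses on printed film: inverting the
image (lesions are sometimes easier to spot in the negative), adjusting
brightness and contrast, and measuring a lesion in millimetres.

Conventions (the source material leaves them open, so they are declared
here and tested):

* contrast pivots about mid-range ``max_range / 2`` — a pure gain change
  then preserves mean brightness;
* integer-typed outputs are rounded half-up;
* physical distances use the per-axis pixel spacing (anisotropic safe) and
  refuse when spacing is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import BoundsError, MissingSpacingError, ParameterError
from .image_io import GrayImage

__all__ = ["MeasurementResult", "negative", "adjust_brightness_contrast", "measure"]


@dataclass(frozen=True)
class MeasurementResult:
    """Distance between two pixels, in pixels and (when possible) in mm."""

    p1: Tuple[int, int]
    p2: Tuple[int, int]
    distance_px: float
    distance_mm: Optional[float]


def _is_integer_image(img: GrayImage) -> bool:
    return np.issubdtype(img.pixels.dtype, np.integer)


def _finalize(img: GrayImage, out: np.ndarray) -> GrayImage:
    out = np.clip(out, 0, img.max_range)
    if _is_integer_image(img):
        out = np.floor(out + 0.5).astype(img.pixels.dtype)  # half-up
    return GrayImage(pixels=out, spacing_mm=img.spacing_mm,
                     bit_depth=img.bit_depth, source_id=img.source_id)


def negative(img: GrayImage) -> GrayImage:
    """Photographic negative: ``max_range - value``.  An involution."""
    out = img.max_range - img.astype_float()
    return _finalize(img, out)


def adjust_brightness_contrast(img: GrayImage, brightness: float = 0.0,
                               contrast: float = 1.0) -> GrayImage:
    """Additive brightness and multiplicative contrast about mid-range.

    ``out = clip(contrast * (in - mid) + mid + brightness, 0, max_range)``
    with ``mid = max_range / 2``; identity at ``contrast=1, brightness=0``.
    """
    if not contrast > 0:
        raise ParameterError(f"contrast gain must be > 0, got {contrast}")
    mid = img.max_range / 2.0
    out = contrast * (img.astype_float() - mid) + mid + brightness
    return _finalize(img, out)


def measure(img: GrayImage, p1: Tuple[int, int], p2: Tuple[int, int],
            require_mm: bool = False) -> MeasurementResult:
    """Euclidean distance between two pixel coordinates.

    ``distance_mm`` uses the per-axis spacing when the image carries one:
    ``sqrt((dr * row_mm)**2 + (dc * col_mm)**2)``.  With ``require_mm`` a
    missing spacing is an error instead of a silently absent value.
    """
    for p in (p1, p2):
        r, c = p
        if not (0 <= r < img.rows and 0 <= c < img.cols):
            raise BoundsError(f"point {p} outside image of shape {(img.rows, img.cols)}")
    dr = float(p2[0] - p1[0])
    dc = float(p2[1] - p1[1])
    dist_px = math.hypot(dr, dc)
    dist_mm: Optional[float] = None
    if img.spacing_mm is not None:
        row_mm, col_mm = img.spacing_mm
        dist_mm = math.hypot(dr * row_mm, dc * col_mm)
    elif require_mm:
        raise MissingSpacingError("image has no pixel spacing; cannot report mm")
    return MeasurementResult(p1=tuple(p1), p2=tuple(p2),
                             distance_px=dist_px, distance_mm=dist_mm)
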