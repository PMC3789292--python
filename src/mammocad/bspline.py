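"""Cubic B-spline contrast enhancement by recursive inverse filtering.

A sampled image s[k] is represented on the cubic B-spline basis,
``s[k] = sum_l c[l] * beta3(k - l)``, where beta3 sampled at the integers
is the three-tap kernel (1, 4, 1)/6.  Finding the coefficients c therefore
means applying the inverse filter

    (B^3)^-1(z) = 6 / (z + 4 + z^-1)
               = -6 z1 / ((1 - z1 z^-1)(1 - z1 z)),   z1 = sqrt(3) - 2,

implemented as a causal recursion (gain 6 and pole z1) followed by an
anticausal recursion, with whole-sample symmetric (mirror) boundary
handling.  The cascade numerator is -6 z1, which gives unit DC gain; the
inverse-filter identity test (reconstructing the image with the direct
(1,4,1)/6 kernel) pins this normalisation.

"Raised-area" enhancement then takes the analytic first derivative of the
continuous spline along X and Y — a first difference of coefficients seen
through the degree-2 spline kernel — rescales each plane to 0–255 for
display, and forms the gradient modulus sqrt(dx^2 + dy^2).  The derivative
is spatially compact, so calcium deposits keep their original size in the
enhanced image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .errors import ParameterError
from .image_io import GrayImage

__all__ = [
    "SplineCoefficients",
    "EnhancedImage",
    "bspline_pole",
    "filter_line",
    "interpolation_coefficients",
    "bspline_reconstruct",
    "enhance",
]

#: direct cubic B-spline kernel sampled at integers
_B3_KERNEL = np.array([1.0, 4.0, 1.0]) / 6.0
#: centred first-derivative taps of the cubic spline at integer points:
#: f'(i) = (c[i+1] - c[i-1]) / 2
_D1_KERNEL = np.array([-0.5, 0.0, 0.5])

_INIT_TOL = 1e-8  # truncation tolerance of the causal-recursion start sum


def bspline_pole(degree: int = 3) -> float:
    """Stable pole of the inverse cubic B-spline filter.

    The denominator z^2 + 4z + 1 has one root inside the unit circle,
    z1 = -2 + sqrt(3) = -0.26794919...; only the cubic case is supported.
    """
    if degree != 3:
        raise ParameterError(f"only the cubic (degree 3) spline is supported, got {degree}")
    return math.sqrt(3.0) - 2.0


def _mirror_index(k: int, n: int) -> int:
    """Whole-sample symmetric index: ... 2 1 0 1 2 ... n-1 n-2 ..."""
    if n == 1:
        return 0
    period = 2 * n - 2
    k = k % period
    return k if k < n else period - k


def _filter_axis(arr: np.ndarray, axis: int, z1: float) -> np.ndarray:
    """Causal + anticausal recursion along one axis of a 2D array."""
    a = np.moveaxis(np.asarray(arr, dtype=np.float64), axis, 0)
    n = a.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 samples along the filtered axis")
    y = 6.0 * a  # gain of the causal filter f_c(z) = 6 / (1 - z1 z^-1)

    # truncated mirror sum initialises the causal pass
    horizon = int(math.ceil(math.log(_INIT_TOL) / math.log(abs(z1))))
    c = np.empty_like(y)
    c0 = y[0].copy()
    zk = 1.0
    for k in range(1, horizon + 1):
        zk *= z1
        c0 += zk * y[_mirror_index(k, n)]
    c[0] = c0
    for k in range(1, n):
        c[k] = y[k] + z1 * c[k - 1]

    # anticausal pass f_ac(z) = -z1 / (1 - z1 z); mirror end condition
    out = np.empty_like(c)
    out[n - 1] = (z1 / (z1 * z1 - 1.0)) * (c[n - 1] + z1 * c[n - 2])
    for k in range(n - 2, -1, -1):
        out[k] = z1 * (out[k + 1] - c[k])
    return np.moveaxis(out, 0, axis)


def filter_line(line: np.ndarray, z1: float | None = None) -> np.ndarray:
    """Interpolation coefficients of a 1D sequence (length >= 2)."""
    if z1 is None:
        z1 = bspline_pole(3)
    arr = np.asarray(line, dtype=np.float64)
    if arr.ndim != 1:
        raise ParameterError("filter_line expects a 1D sequence")
    return _filter_axis(arr[:, None], 0, z1)[:, 0]


@dataclass
class SplineCoefficients:
    """Cubic-spline interpolation coefficients of an image.

    Filtering ``coeffs`` with the direct (1,4,1)/6 kernel along both axes
    reproduces the source image (interior pixels, 1e-6 relative).
    """

    coeffs: np.ndarray
    pole: float


def interpolation_coefficients(img: GrayImage | np.ndarray) -> SplineCoefficients:
    """Separable row-then-column recursive filtering of the image."""
    arr = img.astype_float() if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ParameterError(f"need a 2D image of at least 2x2, got shape {arr.shape}")
    z1 = bspline_pole(3)
    c = _filter_axis(arr, 1, z1)   # every row
    c = _filter_axis(c, 0, z1)     # every column
    return SplineCoefficients(coeffs=c, pole=z1)


def bspline_reconstruct(coeffs: SplineCoefficients | np.ndarray) -> np.ndarray:
    """Direct filtering with the sampled cubic kernel: the inverse operation."""
    c = coeffs.coeffs if isinstance(coeffs, SplineCoefficients) else np.asarray(coeffs)
    out = correlate1d(c, _B3_KERNEL, axis=0, mode="mirror")
    return correlate1d(out, _B3_KERNEL, axis=1, mode="mirror")


@dataclass
class EnhancedImage:
    """Derivative planes of the spline model and their display rescales.

    ``dx``/``dy`` are the raw analytic derivatives along columns (X) and
    rows (Y); ``dx8``/``dy8``/``modulus`` are affinely rescaled to [0, 255]
    per plane (a constant plane maps to all zeros).  The modulus is formed
    from the un-rescaled derivatives, preserving gradient geometry.
    """

    dx: np.ndarray
    dy: np.ndarray
    dx8: np.ndarray
    dy8: np.ndarray
    modulus: np.ndarray


def _rescale_255(plane: np.ndarray) -> np.ndarray:
    lo, hi = float(plane.min()), float(plane.max())
    # a (numerically) constant plane carries no contrast to stretch: map to 0
    # rather than amplifying sub-1e-6 recursion round-off to full scale
    if hi - lo < 1e-6:
        return np.zeros_like(plane)
    return np.clip((plane - lo) * (255.0 / (hi - lo)), 0.0, 255.0)


def enhance(img: GrayImage) -> EnhancedImage:
    """Raised-area enhancement: spline derivatives and gradient modulus."""
    c = interpolation_coefficients(img).coeffs
    # d/dx at pixel centres: derivative taps along the X axis, direct cubic
    # kernel along the other axis (separable evaluation of grad f)
    dx = correlate1d(c, _D1_KERNEL, axis=1, mode="mirror")
    dx = correlate1d(dx, _B3_KERNEL, axis=0, mode="mirror")
    dy = correlate1d(c, _D1_KERNEL, axis=0, mode="mirror")
    dy = correlate1d(dy, _B3_KERNEL, axis=1, mode="mirror")
    modulus = np.hypot(dx, dy)
    return EnhancedImage(dx=dx, dy=dy,
                         dx8=_rescale_255(dx), dy8=_rescale_255(dy),
                         modulus=_rescale_255(modulus))
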