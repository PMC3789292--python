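"""Microcalcification detection by 2D least-squares linear prediction.

Breast parenchyma is locally smooth, so a pixel is well predicted from its
neighbours; a microcalcification is a tiny discontinuity the predictor
cannot follow.  At every pixel, prediction coefficients a_ij are fitted by
least squares over a sliding estimation window, using a causal quadrant
support of (region_rows x region_cols) past neighbours for the forward
predictor and the mirrored anticausal support for the backward predictor —
the same pair of prediction errors a 2D lattice structure parameterises,
computed here directly from the normal equations (with a small ridge
stabiliser) rather than through order-recursive lattice updates.

Stationarity is scored per pixel as

    gamma = cos^2(theta) = 1 - (e_f^2 + e_b^2) / (2 x^2),   clamped to [0, 1],

the squared cosine of the angle between the signal and its projection onto
the prediction space, with the forward/backward error energies averaged
and normalised by the local signal energy.  gamma is 1 wherever the image
is exactly predictable (constants, ramps) and dips at discontinuities.
Energies are per-pixel by default so the low-gamma footprint of an anomaly
stays as compact as the anomaly itself; ``energy_window`` > 1 switches to
patch-summed energies.  Border pixels without full support are assigned
gamma = 1 (never detected).

Pixels with gamma below a threshold gamma_0 are grouped by region growing
(connected components); regions smaller than about 5 pixels are discarded
as noise, per the usual false-positive control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.ndimage import label as cc_label, uniform_filter

from .errors import ConfigurationError, ParameterError
from .image_io import GrayImage

__all__ = [
    "LatticeConfig",
    "GammaMap",
    "Roi",
    "predict_errors",
    "detect_microcalcifications",
    "region_grow",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Prediction-support geometry and detection thresholds.

    ``region_rows x region_cols`` is the causal quadrant support (the
    (m+1, n+1) region; the current pixel itself is excluded), fitted over a
    ``train_window``-sided sliding window.  ``ridge`` scales the diagonal
    stabiliser of the normal equations relative to the matrix trace.
    ``energy_window`` is the side of the patch over which prediction-error
    and signal energies are summed before forming gamma (1 = per pixel).
    """

    region_rows: int = 3
    region_cols: int = 3
    train_window: int = 15
    gamma_threshold: float = 0.90
    ridge: float = 1e-6
    min_region_px: int = 5
    connectivity: int = 8
    energy_window: int = 1

    def __post_init__(self) -> None:
        if self.region_rows < 2 or self.region_cols < 2:
            raise ParameterError("prediction support must be at least 2x2")
        if not (0.0 < self.gamma_threshold < 1.0):
            raise ParameterError(f"gamma_threshold must lie in (0,1), got {self.gamma_threshold}")
        if self.min_region_px < 1:
            raise ParameterError("min_region_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.train_window < max(self.region_rows, self.region_cols) + 1:
            raise ParameterError("train_window too small for the prediction support")
        if self.energy_window < 1 or self.energy_window % 2 == 0:
            raise ParameterError("energy_window must be an odd positive integer")


@dataclass
class GammaMap:
    gamma: np.ndarray           # stationarity score in [0, 1]
    forward_error: np.ndarray   # e_f = x - x_hat_forward
    backward_error: np.ndarray  # e_b = x - x_hat_backward


@dataclass
class Roi:
    """One connected low-gamma region."""

    pixels: np.ndarray              # (k, 2) array of (row, col)
    centroid: Tuple[float, float]
    area_px: int
    bbox: Tuple[int, int, int, int]  # rmin, cmin, rmax, cmax (inclusive)


def _support_offsets(rows: int, cols: int) -> List[Tuple[int, int]]:
    """Causal quadrant offsets (di, dj), di in [0, m], dj in [0, n], minus (0, 0)."""
    return [(di, dj) for di in range(rows) for dj in range(cols) if (di, dj) != (0, 0)]


def _shift(x: np.ndarray, di: int, dj: int) -> np.ndarray:
    """x shifted so out[i, j] = x[i - di, j - dj]; edge-padded (borders masked later)."""
    out = np.roll(np.roll(x, di, axis=0), dj, axis=1)
    return out


def _one_side_errors(x: np.ndarray, offsets: List[Tuple[int, int]],
                     cfg: LatticeConfig) -> np.ndarray:
    """Prediction error plane for one support orientation.

    Normal equations are assembled from sliding-window means of regressor
    products (uniform filters), stabilised with ridge * trace / p on the
    diagonal, and solved per pixel in a single batched call.
    """
    p = len(offsets)
    shifted = np.stack([_shift(x, di, dj) for (di, dj) in offsets], axis=-1)  # (R, C, p)
    w = cfg.train_window

    A = np.empty(x.shape + (p, p), dtype=np.float64)
    b = np.empty(x.shape + (p,), dtype=np.float64)
    for i in range(p):
        for j in range(i, p):
            g = uniform_filter(shifted[..., i] * shifted[..., j], size=w, mode="nearest")
            A[..., i, j] = g
            A[..., j, i] = g
        b[..., i] = uniform_filter(shifted[..., i] * x, size=w, mode="nearest")

    trace = np.einsum("...ii->...", A)
    lam = cfg.ridge * trace / p
    A[..., np.arange(p), np.arange(p)] += lam[..., None]
    coef = np.linalg.solve(A, b[..., None])[..., 0]    # (R, C, p)
    x_hat = np.einsum("rcp,rcp->rc", shifted, coef)
    return x - x_hat


def predict_errors(img: GrayImage, cfg: LatticeConfig | None = None) -> GammaMap:
    """Forward/backward prediction-error planes and the gamma map."""
    if cfg is None:
        cfg = LatticeConfig()
    x = img.astype_float()
    if min(x.shape) <= cfg.train_window:
        raise ConfigurationError(
            f"train_window {cfg.train_window} does not fit image of shape {x.shape}")

    fwd = _support_offsets(cfg.region_rows, cfg.region_cols)
    bwd = [(-di, -dj) for (di, dj) in fwd]
    e_f = _one_side_errors(x, fwd, cfg)
    e_b = _one_side_errors(x, bwd, cfg)

    # pixels whose support or estimation window leaves the image: not scored
    m_r, m_c = cfg.region_rows - 1, cfg.region_cols - 1
    half = cfg.train_window // 2
    top, left = m_r + half, m_c + half
    valid = np.zeros_like(x, dtype=bool)
    if x.shape[0] > 2 * top and x.shape[1] > 2 * left:
        valid[top:x.shape[0] - top, left:x.shape[1] - left] = True
    e_f = np.where(valid, e_f, 0.0)
    e_b = np.where(valid, e_b, 0.0)

    err_energy = 0.5 * (e_f ** 2 + e_b ** 2)
    sig_energy = x ** 2
    if cfg.energy_window > 1:
        err_energy = uniform_filter(err_energy, size=cfg.energy_window, mode="nearest")
        sig_energy = uniform_filter(sig_energy, size=cfg.energy_window, mode="nearest")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = err_energy / sig_energy
    rel = np.where(sig_energy > 0, rel, np.where(err_energy > 0, np.inf, 0.0))
    # the ridge stabiliser biases a perfect predictor by O(ridge); snap the
    # resulting ~1e-14 relative energies to exact stationarity
    rel = np.where(rel < 1e-10, 0.0, rel)
    gamma = np.clip(1.0 - rel, 0.0, 1.0)
    gamma[~valid] = 1.0
    return GammaMap(gamma=gamma, forward_error=e_f, backward_error=e_b)


def region_grow(mask: np.ndarray, min_region_px: int = 5,
                connectivity: int = 8) -> List[Roi]:
    """Connected components of a binary mask, size-filtered, sorted by area."""
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    else:
        raise ParameterError("connectivity must be 4 or 8")
    comp, ncomp = cc_label(np.asarray(mask, dtype=bool), structure=structure)
    rois: List[Roi] = []
    for i in range(1, ncomp + 1):
        rs, cs = np.nonzero(comp == i)
        if rs.size < min_region_px:
            continue
        pixels = np.column_stack([rs, cs])
        rois.append(Roi(
            pixels=pixels,
            centroid=(float(rs.mean()), float(cs.mean())),
            area_px=int(rs.size),
            bbox=(int(rs.min()), int(cs.min()), int(rs.max()), int(cs.max())),
        ))
    rois.sort(key=lambda r: (-r.area_px, r.bbox))
    return rois


def detect_microcalcifications(img: GrayImage, cfg: LatticeConfig | None = None) -> List[Roi]:
    """Threshold the gamma map at gamma_0 and size-filter the grown regions."""
    if cfg is None:
        cfg = LatticeConfig()
    gm = predict_errors(img, cfg)
    mask = gm.gamma < cfg.gamma_threshold
    return region_grow(mask, cfg.min_region_px, cfg.connectivity)
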