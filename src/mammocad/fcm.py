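"""Fuzzy C-means segmentation of pixel intensities.

Mass contours in a mammogram separate cleanly when the image is softly
clustered by intensity: each pixel x_k receives a membership u_ik in [0, 1]
for each of c classes, and the algorithm alternates

    u_ik = [ sum_j (d_ik / d_jk)^(p/(m-1)) ]^-1          (membership update)
    v_i  = sum_k u_ik^m x_k / sum_k u_ik^m               (centroid update)

minimising the weighted within-class objective

    J(U, V) = sum_i sum_k u_ik^m d(x_k, v_i)^p

with d the Euclidean distance.  The classical squared-error form (p = 2) is
the default; ``norm_power=1`` selects the unsquared variant.  Iteration
stops when the summed centroid displacement E_t = sum_i |v_i(t+1) - v_i(t)|
drops below epsilon.  A pixel coinciding with a centroid takes the limit
membership: 1 for that class, 0 elsewhere.

The class count and initial centroids come from histogram analysis
(:func:`histogram_init`); the soft partition is hardened by maximum
membership, and mass contours are traced from the hard label map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.signal import find_peaks

from .errors import DegenerateInputError, DimensionError, ParameterError
from .image_io import GrayImage

__all__ = [
    "FCMConfig",
    "FCMResult",
    "fcm_fit",
    "histogram_init",
    "hard_segmentation",
    "extract_mass_contour",
]


@dataclass
class FCMConfig:
    """Parameters of the fuzzy C-means fit.

    ``m_fuzz`` is the fuzzifier m (> 1 for the soft update to be defined;
    m -> 1 approaches hard k-means).  ``epsilon`` is the convergence
    tolerance on the summed centroid displacement, in intensity units.
    ``norm_power`` selects the distance power p in the objective (2 =
    squared Euclidean, the default; 1 = unsquared).
    """

    c: int
    V0: Sequence[float]
    m_fuzz: float = 2.0
    epsilon: float = 1e-3
    max_iter: int = 100
    norm_power: int = 2

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ParameterError(f"need at least 2 classes, got c={self.c}")
        if not self.m_fuzz > 1:
            raise ParameterError(f"m_fuzz must be > 1, got {self.m_fuzz}")
        if not self.epsilon > 0:
            raise ParameterError("epsilon must be > 0")
        if self.norm_power not in (1, 2):
            raise ParameterError(f"norm_power must be 1 or 2, got {self.norm_power}")
        v0 = [float(v) for v in self.V0]
        if len(v0) != self.c:
            raise ParameterError(f"V0 must list {self.c} centroids, got {len(v0)}")
        if len(set(v0)) != len(v0):
            raise ParameterError(f"initial centroids must be distinct, got {v0}")
        self.V0 = v0


@dataclass
class FCMResult:
    U: np.ndarray          # (c, n) memberships, columns sum to 1
    V: np.ndarray          # (c,) centroids
    labels: np.ndarray     # (n,) argmax class per sample
    J_trace: np.ndarray    # objective per iteration
    E_trace: np.ndarray    # summed centroid displacement per iteration
    iterations: int


def _memberships(x: np.ndarray, V: np.ndarray, m: float, p: int) -> np.ndarray:
    """Membership update; exact one-hot limit where a sample hits a centroid."""
    d = np.abs(x[None, :] - V[:, None])            # (c, n) Euclidean distance, scalar data
    U = np.empty_like(d)
    zero_cols = np.any(d == 0.0, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = d[:, None, :] / d[None, :, :]      # d_ik / d_jk
        U = 1.0 / np.sum(ratio ** (p / (m - 1.0)), axis=1)
    if np.any(zero_cols):
        cols = np.nonzero(zero_cols)[0]
        U[:, cols] = 0.0
        U[np.argmin(d[:, cols], axis=0), cols] = 1.0
    return U


def _objective(x: np.ndarray, U: np.ndarray, V: np.ndarray, m: float, p: int) -> float:
    d = np.abs(x[None, :] - V[:, None])
    return float(np.sum((U ** m) * d ** p))


def fcm_fit(data: Sequence[float] | np.ndarray, cfg: FCMConfig) -> FCMResult:
    """Run the alternating FCM iteration on scalar intensities.

    Deterministic given (data, cfg): there is no internal randomness.
    """
    x = np.asarray(data, dtype=np.float64).ravel()
    if x.size == 0:
        raise ParameterError("empty data")
    if x.size < cfg.c:
        raise ParameterError(f"need at least c={cfg.c} samples, got {x.size}")
    V = np.asarray(cfg.V0, dtype=np.float64).copy()
    m, p = cfg.m_fuzz, cfg.norm_power

    J_trace: List[float] = []
    E_trace: List[float] = []
    U = _memberships(x, V, m, p)
    it = 0
    for it in range(1, cfg.max_iter + 1):
        w = U ** m
        denom = w.sum(axis=1)
        V_new = np.where(denom > 0, (w * x[None, :]).sum(axis=1) / np.where(denom > 0, denom, 1.0), V)
        E = float(np.sum(np.abs(V_new - V)))
        V = V_new
        U = _memberships(x, V, m, p)
        J_trace.append(_objective(x, U, V, m, p))
        E_trace.append(E)
        if E < cfg.epsilon:
            break
    labels = np.argmax(U, axis=0)
    return FCMResult(U=U, V=V, labels=labels,
                     J_trace=np.asarray(J_trace), E_trace=np.asarray(E_trace),
                     iterations=it)


# ---------------------------------------------------------------------------
# histogram-driven initialisation
# ---------------------------------------------------------------------------

#: histogram analysis constants: 256 bins, moving-average width 5,
#: peak prominence at 1% of the pixel count
_HIST_BINS = 256
_SMOOTH_WIDTH = 5
_PROMINENCE_FRAC = 0.01


def histogram_init(img: GrayImage, c_max: int = 5) -> FCMConfig:
    """Choose (c, V0) from the smoothed intensity histogram.

    Prominent local maxima of a 256-bin histogram (moving-average smoothed,
    prominence >= 1% of the pixel count) become the candidate centroids;
    c is clipped to [2, c_max].
    """
    if c_max < 2:
        raise ParameterError(f"c_max must be >= 2, got {c_max}")
    x = img.astype_float().ravel()
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise DegenerateInputError("constant image: histogram has a single value")

    if np.issubdtype(img.pixels.dtype, np.integer) and img.max_range <= _HIST_BINS - 1:
        edges = np.arange(_HIST_BINS + 1) - 0.5
    else:
        edges = np.linspace(0.0, float(img.max_range), _HIST_BINS + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist, _ = np.histogram(x, bins=edges)
    kernel = np.ones(_SMOOTH_WIDTH) / _SMOOTH_WIDTH
    smooth = np.convolve(hist.astype(np.float64), kernel, mode="same")

    prominence = _PROMINENCE_FRAC * x.size
    padded = np.concatenate(([0.0], smooth, [0.0]))  # let edge bins count as peaks
    peaks, props = find_peaks(padded, prominence=prominence)
    peaks -= 1
    order = np.argsort(props["prominences"])[::-1]
    peaks = peaks[order][: c_max]
    V0 = sorted(float(centers[p]) for p in peaks)

    if len(V0) < 2:
        # unimodal histogram: supplement with the far end of the occupied range
        anchor = V0[0] if V0 else float(centers[int(np.argmax(smooth))])
        extra = hi if abs(hi - anchor) >= abs(anchor - lo) else lo
        V0 = sorted({anchor, float(extra)})
        if len(V0) < 2:  # pathological; fall back to range endpoints
            V0 = sorted({lo, hi})
    return FCMConfig(c=len(V0), V0=V0)


def hard_segmentation(res: FCMResult, shape: Tuple[int, int]) -> np.ndarray:
    """Maximum-membership hardening: pixel k -> argmax_i u_ik, reshaped.

    Ties break to the lowest class index.
    """
    rows, cols = shape
    n = res.U.shape[1]
    if rows * cols != n:
        raise DimensionError(f"shape {shape} incompatible with {n} samples")
    return np.argmax(res.U, axis=0).reshape(rows, cols)


# ---------------------------------------------------------------------------
# contour extraction (Moore boundary tracing, 8-connected components)
# ---------------------------------------------------------------------------

# clockwise Moore neighbourhood starting west
_DIRS = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _trace_boundary(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Closed boundary polyline of a single 8-connected component."""
    rs, cs = np.nonzero(mask)
    start = (int(rs[0]), int(cs[0]))  # topmost, then leftmost (nonzero is row-major)

    def inside(p: Tuple[int, int]) -> bool:
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and bool(mask[r, c])

    contour = [start]
    backtrack = (start[0], start[1] - 1)  # outside: start is leftmost in its row
    cur = start
    seen = set()
    while True:
        state = (cur, backtrack)
        if state in seen:
            break
        seen.add(state)
        base = _DIRS.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = None
        for k in range(1, len(_DIRS) + 1):
            d = _DIRS[(base + k) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if inside(cand):
                prev_d = _DIRS[(base + k - 1) % 8]
                nxt = cand
                backtrack = (cur[0] + prev_d[0], cur[1] + prev_d[1])
                break
        if nxt is None:  # isolated pixel
            break
        cur = nxt
        if cur == start and (cur, backtrack) in seen:
            break
        contour.append(cur)
    if len(contour) > 1 and contour[-1] == start:
        contour.pop()
    contour.append(start)  # explicit closure
    return contour


def extract_mass_contour(labels: np.ndarray, class_id: int) -> List[List[Tuple[int, int]]]:
    """Closed boundary polylines of the 8-connected components of a class.

    An absent class yields an empty list.  Each contour is a list of
    0-based (row, col) points whose first and last entries coincide.
    """
    labels = np.asarray(labels)
    mask = labels == class_id
    if not mask.any():
        return []
    structure = np.ones((3, 3), dtype=int)
    comp, ncomp = cc_label(mask, structure=structure)
    contours = []
    for i in range(1, ncomp + 1):
        contours.append(_trace_boundary(comp == i))
    return contours
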