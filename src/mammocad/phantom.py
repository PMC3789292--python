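"""Seeded synthetic mammographic phantoms with exact ground truth.

The generator emulates the four BI-RADS breast-density backgrounds —
predominantly fatty, fatty, heterogeneously dense, dense — as smoothed
correlated noise fields whose mean intensity, texture amplitude and benign
"clutter" rate rise with density (dense parenchyma is brighter and more
structured, which is exactly why detection is harder there).  Masses are
planted as soft-edged discs, optionally with radial spicule rays;
microcalcifications as small high-contrast square blocks (1–4 px by
default).  Clutter spots are small moderate-contrast structures that are
NOT recorded as lesions: they model benign fibrous crossings and vascular
calcifications, the dominant source of false positives.

Everything is driven by one seed and is bit-reproducible.  The per-tissue
parameter table is a synthetic calibration, not a clinical measurement;
intensities live on a 12-bit scale (typical for FFDM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError, PhantomSpecError
from .image_io import GrayImage

__all__ = ["TISSUE_PARAMS", "LesionSpec", "PhantomSpec", "TruthLesion", "PhantomTruth", "generate"]

#: synthetic per-tissue calibration (12-bit intensity scale):
#: mean background level, texture amplitude (sd of the smoothed field) and
#: expected count of benign clutter spots per 256x256 field of view
TISSUE_PARAMS: Dict[str, Dict[str, float]] = {
    "predominantly_fatty":    {"mean": 60.0,  "texture_amp": 4.0,  "clutter_rate": 0.5},
    "fatty":                  {"mean": 90.0,  "texture_amp": 7.0,  "clutter_rate": 1.5},
    "heterogeneously_dense":  {"mean": 140.0, "texture_amp": 14.0, "clutter_rate": 4.0},
    "dense":                  {"mean": 180.0, "texture_amp": 20.0, "clutter_rate": 6.0},
}

_TEXTURE_SIGMA_PX = 8.0        # correlation length of the background field
_CLUTTER_CONTRAST = (2.6, 4.0)     # relative to the background mean
_DEFAULT_SPACING = (0.07, 0.07)    # mm, typical FFDM detector pitch


@dataclass(frozen=True)
class LesionSpec:
    """One planted lesion.

    ``diameter_px`` is the mass diameter (soft disc) or the side of the
    microcalcification block; ``contrast`` is the additive intensity above
    local background.
    """

    kind: str                       # mass | microcalcification | distortion
    centroid: Tuple[int, int]       # (row, col)
    diameter_px: float
    contrast: float
    spiculated: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("mass", "microcalcification", "distortion"):
            raise ParameterError(f"unknown lesion kind {self.kind!r}")
        if not self.contrast > 0:
            raise PhantomSpecError("lesion contrast must be > 0")
        if not self.diameter_px > 0:
            raise PhantomSpecError("lesion diameter must be > 0")


@dataclass
class PhantomSpec:
    tissue: str = "fatty"
    rows: int = 256
    cols: int = 256
    background_mean: Optional[float] = None          # None -> per-tissue default
    background_texture_scale: Optional[float] = None
    clutter_rate: Optional[float] = None
    lesions: List[LesionSpec] = field(default_factory=list)
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUE_PARAMS:
            raise ParameterError(f"unknown tissue class {self.tissue!r}")
        if self.rows < 32 or self.cols < 32:
            raise PhantomSpecError("phantom must be at least 32x32")
        for les in self.lesions:
            r, c = les.centroid
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise PhantomSpecError(f"lesion centroid {les.centroid} outside "
                                       f"{self.rows}x{self.cols} phantom")


@dataclass
class TruthLesion:
    kind: str
    centroid: Tuple[float, float]
    mask: np.ndarray                # (k, 2) pixel coordinates


@dataclass
class PhantomTruth:
    tissue: str
    lesions: List[TruthLesion]


def _mass_profile(shape: Tuple[int, int], centroid: Tuple[int, int],
                  radius: float, contrast: float) -> np.ndarray:
    """Plateau disc with a ~1 px linear shoulder, so the mean excess over
    the truth mask is close to the requested contrast."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r = np.hypot(rr - centroid[0], cc - centroid[1])
    inner = max(radius - 1.0, 0.5)
    prof = np.clip((radius + 1.0 - r) / (radius + 1.0 - inner), 0.0, 1.0)
    return contrast * prof


def _spicule_rays(shape: Tuple[int, int], centroid: Tuple[int, int], radius: float,
                  contrast: float, rng: np.random.Generator) -> np.ndarray:
    """8–16 radial rays of decaying contrast, one pixel wide."""
    out = np.zeros(shape)
    n_rays = int(rng.integers(8, 17))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n_rays)
    length = 2.5 * radius
    for ang in angles:
        s = np.arange(radius, radius + length, 0.5)
        rs = np.round(centroid[0] + s * np.sin(ang)).astype(int)
        cs = np.round(centroid[1] + s * np.cos(ang)).astype(int)
        keep = (rs >= 0) & (rs < shape[0]) & (cs >= 0) & (cs < shape[1])
        decay = contrast * 0.6 * np.exp(-(s - radius) / (0.6 * length))
        np.maximum.at(out, (rs[keep], cs[keep]), decay[keep])
    return out


def _block_mask(shape: Tuple[int, int], centroid: Tuple[int, int], side: int) -> np.ndarray:
    r0 = centroid[0] - (side - 1) // 2
    c0 = centroid[1] - (side - 1) // 2
    mask = np.zeros(shape, dtype=bool)
    mask[max(r0, 0): min(r0 + side, shape[0]), max(c0, 0): min(c0 + side, shape[1])] = True
    return mask


def generate(spec: PhantomSpec) -> Tuple[GrayImage, PhantomTruth]:
    """Render a phantom and its exact ground truth.

    The background is a seeded smoothed-noise field around the per-tissue
    mean; lesions are added on top; clutter spots (never in the truth) and
    white noise complete the image.  Fixed seed -> bit-identical output.
    """
    params = TISSUE_PARAMS[spec.tissue]
    mean = spec.background_mean if spec.background_mean is not None else params["mean"]
    tex = (spec.background_texture_scale if spec.background_texture_scale is not None
           else params["texture_amp"])
    clutter_rate = spec.clutter_rate if spec.clutter_rate is not None else params["clutter_rate"]
    shape = (spec.rows, spec.cols)
    rng = np.random.default_rng(spec.seed)

    field_ = gaussian_filter(rng.standard_normal(shape), sigma=_TEXTURE_SIGMA_PX, mode="reflect")
    sd = field_.std()
    if sd > 0:
        field_ *= tex / sd
    image = mean + field_

    truths: List[TruthLesion] = []
    for les in spec.lesions:
        if les.kind == "microcalcification":
            side = max(int(round(les.diameter_px)), 1)
            mask = _block_mask(shape, les.centroid, side)
            image = np.where(mask, image + les.contrast, image)
        else:  # mass / distortion: soft-edged disc, optional spicules
            radius = les.diameter_px / 2.0
            prof = _mass_profile(shape, les.centroid, radius, les.contrast)
            if les.spiculated:
                prof = np.maximum(prof, _spicule_rays(shape, les.centroid, radius,
                                                      les.contrast, rng))
            image = image + prof
            rr, cc = np.ogrid[: shape[0], : shape[1]]
            mask = np.hypot(rr - les.centroid[0], cc - les.centroid[1]) <= radius
        rs, cs = np.nonzero(mask)
        truths.append(TruthLesion(kind=les.kind,
                                  centroid=(float(les.centroid[0]), float(les.centroid[1])),
                                  mask=np.column_stack([rs, cs])))

    # benign structural clutter (vascular/benign calcifications): tiny very
    # bright spots, excluded from the truth — the dominant FP source
    area_scale = (spec.rows * spec.cols) / (256.0 * 256.0)
    n_clutter = int(rng.poisson(clutter_rate * area_scale))
    for _ in range(n_clutter):
        r = int(rng.integers(12, spec.rows - 12))
        c = int(rng.integers(12, spec.cols - 12))
        side = int(rng.integers(1, 3))
        contrast = float(rng.uniform(*_CLUTTER_CONTRAST)) * mean
        image[r: r + side, c: c + side] += contrast

    image = image + rng.normal(0.0, spec.noise_sd, size=shape)
    image = np.clip(image, 0.0, 4095.0)
    gray = GrayImage(pixels=image, spacing_mm=_DEFAULT_SPACING, bit_depth=12,
                     source_id=f"phantom:{spec.tissue}:seed={spec.seed}")
    return gray, PhantomTruth(tissue=spec.tissue, lesions=truths)
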