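"""Detection scoring and the risk-guided two-pass detection rule.

TPD (true positive detections) is the percentage of true lesions that were
detected, ``100 * TP / (TP + FN)``; FPD is the percentage of detections
that are false, ``100 * FP / (TP + FP)`` — with no detections at all, FPD
is reported as 0 and flagged undefined.  Detections are matched to ground
truth greedily, nearest centroid first, one-to-one, within a pixel
tolerance.

The two-pass rule uses per-patient risk context from the health record:
when malignancy is suspected and the first detection pass finds lesions,
they are returned highlighted for the reader; when the suspected case
comes back empty, the detector is re-run with a more sensitive threshold
and the union of passes is returned (recovering subtle lesions at the cost
of sensitivity).  When malignancy is not suspected, a stricter second pass
is intersected with the first (pixel overlap), suppressing weak false
positives while strong detections survive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .adaptive import LatticeConfig, Roi, detect_microcalcifications
from .errors import ParameterError
from .image_io import GrayImage
from .phantom import PhantomTruth
from .sr_report import LesionFinding

__all__ = ["MatchResult", "EhrContext", "match_detections", "ehr_guided_detect",
           "SECOND_PASS_DELTA"]

#: default gamma_0 shift of the second pass (+ when sensitising, - when stricter)
SECOND_PASS_DELTA = 0.05


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: List[Tuple[int, int]]       # (detection index, truth index)
    tpd_pct: float
    fpd_pct: float
    tpd_defined: bool = True
    fpd_defined: bool = True


def _centroid_of(obj) -> Tuple[float, float]:
    c = obj.centroid
    return (float(c[0]), float(c[1]))


def match_detections(detections: Sequence, truth: PhantomTruth | Sequence,
                     tol_px: float = 5.0) -> MatchResult:
    """Greedy one-to-one nearest-centroid matching within ``tol_px``.

    ``detections`` may be Roi or LesionFinding objects (anything with a
    ``centroid``); ``truth`` a :class:`PhantomTruth` or a plain sequence of
    truth lesions.
    """
    if not tol_px > 0:
        raise ParameterError(f"tol_px must be > 0, got {tol_px}")
    truths = truth.lesions if isinstance(truth, PhantomTruth) else list(truth)
    det_c = np.array([_centroid_of(d) for d in detections], dtype=float).reshape(-1, 2)
    tru_c = np.array([_centroid_of(t) for t in truths], dtype=float).reshape(-1, 2)
    nd, nt = det_c.shape[0], tru_c.shape[0]

    pairs: List[Tuple[int, int]] = []
    if nd and nt:
        dist = np.linalg.norm(det_c[:, None, :] - tru_c[None, :, :], axis=-1)
        free_d = np.ones(nd, dtype=bool)
        free_t = np.ones(nt, dtype=bool)
        while True:
            masked = np.where(np.outer(free_d, free_t), dist, np.inf)
            i, j = np.unravel_index(np.argmin(masked), masked.shape)
            if not np.isfinite(masked[i, j]) or masked[i, j] > tol_px:
                break
            pairs.append((int(i), int(j)))
            free_d[i] = free_t[j] = False

    tp = len(pairs)
    fp = nd - tp
    fn = nt - tp
    tpd_defined = (tp + fn) > 0
    fpd_defined = (tp + fp) > 0
    tpd = 100.0 * tp / (tp + fn) if tpd_defined else 0.0
    fpd = 100.0 * fp / (tp + fp) if fpd_defined else 0.0
    return MatchResult(tp=tp, fp=fp, fn=fn, pairs=pairs, tpd_pct=tpd, fpd_pct=fpd,
                       tpd_defined=tpd_defined, fpd_defined=fpd_defined)


@dataclass
class EhrContext:
    """Per-study risk context extracted from the health record."""

    malignancy_suspected: bool = False
    notes: str = ""


def _roi_to_finding(roi: Roi, img: GrayImage, highlight: bool,
                    laterality: str, projection: str) -> LesionFinding:
    size_mm: Optional[float] = None
    if img.spacing_mm is not None:
        # equivalent-circle diameter in mm, averaged over the two axes
        mean_sp = 0.5 * (img.spacing_mm[0] + img.spacing_mm[1])
        size_mm = 2.0 * float(np.sqrt(roi.area_px / np.pi)) * mean_sp
    return LesionFinding(kind="microcalcification", laterality=laterality,
                         projection=projection, centroid=roi.centroid, size_mm=size_mm,
                         source_algorithm="adaptive", highlight=highlight)


def _union(rois_a: List[Roi], rois_b: List[Roi], shape, min_px: int, conn: int) -> List[Roi]:
    from .adaptive import region_grow
    mask = np.zeros(shape, dtype=bool)
    for roi in rois_a + rois_b:
        mask[roi.pixels[:, 0], roi.pixels[:, 1]] = True
    return region_grow(mask, min_px, conn)


def _intersect(primary: List[Roi], secondary: List[Roi], shape) -> List[Roi]:
    """Keep primary ROIs that share at least one pixel with a secondary ROI."""
    mask_b = np.zeros(shape, dtype=bool)
    for roi in secondary:
        mask_b[roi.pixels[:, 0], roi.pixels[:, 1]] = True
    return [roi for roi in primary if mask_b[roi.pixels[:, 0], roi.pixels[:, 1]].any()]


def ehr_guided_detect(img: GrayImage, ehr: EhrContext,
                      cfg: LatticeConfig | None = None,
                      cfg_second: LatticeConfig | None = None,
                      laterality: str = "L", projection: str = "CC") -> List[LesionFinding]:
    """Two-pass adaptive detection gated by the patient's risk context."""
    if cfg is None:
        cfg = LatticeConfig()
    first = detect_microcalcifications(img, cfg)
    shape = (img.rows, img.cols)

    if ehr.malignancy_suspected:
        if first:
            rois = first
        else:
            if cfg_second is None:
                cfg_second = replace(
                    cfg, gamma_threshold=min(cfg.gamma_threshold + SECOND_PASS_DELTA, 0.999))
            second = detect_microcalcifications(img, cfg_second)
            rois = _union(first, second, shape, cfg.min_region_px, cfg.connectivity)
        return [_roi_to_finding(r, img, True, laterality, projection) for r in rois]

    if cfg_second is None:
        cfg_second = replace(
            cfg, gamma_threshold=max(cfg.gamma_threshold - SECOND_PASS_DELTA, 1e-3))
    second = detect_microcalcifications(img, cfg_second)
    rois = _intersect(first, second, shape)
    return [_roi_to_finding(r, img, False, laterality, projection) for r in rois]
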