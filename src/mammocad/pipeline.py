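"""End-to-end batch pipeline: load → preprocess → detect → report.

One call (or ``mammocad run``) takes a set of mammograms and a
:class:`PipelineConfig`, runs the selected algorithms on each image, and
writes every artifact — enhanced planes, label maps, ROI JSON, DICOM-SR —
plus a manifest listing each output with its SHA-256 checksum.  The run is
deterministic: identical config, inputs and seed give identical checksums
(report timestamps and SR instance UIDs derive from the run seed and the
report content, not the wall clock).

Per-file failures are recorded in the manifest and do not stop the batch;
the CLI maps them to exit code 1 (2 for fatal errors).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import os
import tomllib
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import adaptive, bspline, fcm, preprocess, sr_report
from .errors import MammocadError
from .evaluation import EhrContext, _roi_to_finding, ehr_guided_detect
from .image_io import GrayImage, load_image, save_image

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("mammocad.pipeline")


@dataclass
class PipelineConfig:
    """Flat, human-editable run configuration (TOML on disk)."""

    algorithms: List[str] = field(default_factory=lambda: ["adaptive"])
    outdir: str = "mammocad_out"
    seed: int = 0
    log_level: str = "INFO"
    # preprocessing (applied before the algorithms when set)
    negative: bool = False
    brightness: float = 0.0
    contrast: float = 1.0
    # fcm block
    fcm_classes: int | str = "auto"   # int or "auto" (histogram analysis)
    fcm_fuzz: float = 2.0
    fcm_eps: float = 1e-3
    fcm_max_iter: int = 100
    # adaptive block
    gamma_threshold: float = 0.90
    min_region_px: int = 5
    train_window: int = 15
    # ehr context (None -> plain single-pass detection)
    ehr_risk: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise MammocadError("at least one algorithm must be selected")
        unknown = set(self.algorithms) - {"fcm", "bspline", "adaptive"}
        if unknown:
            raise MammocadError(f"unknown algorithms: {sorted(unknown)}")

    def lattice_config(self) -> adaptive.LatticeConfig:
        return adaptive.LatticeConfig(gamma_threshold=self.gamma_threshold,
                                      min_region_px=self.min_region_px,
                                      train_window=self.train_window)


def load_config(path: str) -> PipelineConfig:
    """Read a TOML config file; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise MammocadError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _roi_jsonable(roi: adaptive.Roi) -> dict:
    return {"centroid": list(roi.centroid), "area_px": roi.area_px,
            "bbox": list(roi.bbox), "pixels": roi.pixels.tolist()}


def _process_one(path: str, cfg: PipelineConfig, outdir: str) -> Dict[str, str]:
    """Run the configured algorithms on one input; returns artifact paths."""
    stem = os.path.splitext(os.path.basename(path))[0]
    img = load_image(path)
    if cfg.negative:
        img = preprocess.negative(img)
    if cfg.brightness != 0.0 or cfg.contrast != 1.0:
        img = preprocess.adjust_brightness_contrast(img, cfg.brightness, cfg.contrast)

    outputs: Dict[str, str] = {}
    findings: List[sr_report.LesionFinding] = []

    if "bspline" in cfg.algorithms:
        enh = bspline.enhance(img)
        for name, plane in (("dx", enh.dx8), ("dy", enh.dy8), ("mod", enh.modulus)):
            p = os.path.join(outdir, f"{stem}_{name}.png")
            save_image(GrayImage(pixels=np.floor(plane + 0.5).astype(np.int64), bit_depth=8),
                       p, format="png")
            outputs[f"bspline_{name}"] = p

    if "fcm" in cfg.algorithms:
        if cfg.fcm_classes == "auto":
            fcm_cfg = fcm.histogram_init(img)
            fcm_cfg = replace(fcm_cfg, m_fuzz=cfg.fcm_fuzz, epsilon=cfg.fcm_eps,
                              max_iter=cfg.fcm_max_iter)
        else:
            c = int(cfg.fcm_classes)
            lo, hi = float(img.pixels.min()), float(img.pixels.max())
            v0 = list(np.linspace(lo, hi, c))
            fcm_cfg = fcm.FCMConfig(c=c, V0=v0, m_fuzz=cfg.fcm_fuzz,
                                    epsilon=cfg.fcm_eps, max_iter=cfg.fcm_max_iter)
        res = fcm.fcm_fit(img.astype_float().ravel(), fcm_cfg)
        labels = fcm.hard_segmentation(res, (img.rows, img.cols))
        p = os.path.join(outdir, f"{stem}_labels.pgm")
        save_image(GrayImage(pixels=labels.astype(np.int64), bit_depth=8), p, format="pgm")
        outputs["fcm_labels"] = p
        bright = int(np.argmax(res.V))   # lesion candidates: brightest class
        contours = fcm.extract_mass_contour(labels, bright)
        p = os.path.join(outdir, f"{stem}_contours.json")
        with open(p, "w") as fh:
            json.dump([[list(pt) for pt in cont] for cont in contours], fh)
        outputs["fcm_contours"] = p
        for cont in contours:
            pts = np.array(cont, dtype=float)
            closed = [(float(r), float(c)) for r, c in cont]
            findings.append(sr_report.LesionFinding(
                kind="mass", laterality="L", projection="CC",
                centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                contour=closed, source_algorithm="fcm"))

    if "adaptive" in cfg.algorithms:
        lat_cfg = cfg.lattice_config()
        if cfg.ehr_risk is None:
            rois = adaptive.detect_microcalcifications(img, lat_cfg)
            adet = [_roi_to_finding(r, img, False, "L", "CC") for r in rois]
        else:
            ehr = EhrContext(malignancy_suspected=bool(cfg.ehr_risk))
            adet = ehr_guided_detect(img, ehr, lat_cfg)
            rois = adaptive.detect_microcalcifications(img, lat_cfg)
        p = os.path.join(outdir, f"{stem}_rois.json")
        with open(p, "w") as fh:
            json.dump([_roi_jsonable(r) for r in rois], fh)
        outputs["adaptive_rois"] = p
        mask = np.zeros((img.rows, img.cols), dtype=np.int64)
        for roi in rois:
            mask[roi.pixels[:, 0], roi.pixels[:, 1]] = 255
        p = os.path.join(outdir, f"{stem}_mask.png")
        save_image(GrayImage(pixels=mask, bit_depth=8), p, format="png")
        outputs["adaptive_mask"] = p
        findings.extend(adet)

    created = _dt.datetime(2000, 1, 1) + _dt.timedelta(seconds=int(cfg.seed) % (10 ** 9))
    tree = sr_report.build_report(study_id=stem, findings=findings, created=created)
    p = os.path.join(outdir, f"{stem}_report.dcm")
    sr_report.write_sr(tree, p)
    outputs["report"] = p
    outputs["report_sidecar"] = p + ".json"
    return outputs


def run_pipeline(cfg: PipelineConfig, inputs: Sequence[str]) -> dict:
    """Process every input; returns (and writes) the run manifest."""
    logging.basicConfig(
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s %(message)s")
    os.makedirs(cfg.outdir, exist_ok=True)
    entries = []
    for path in inputs:
        log.info("processing %s", path)
        entry: dict = {"input": str(path), "outputs": {}, "error": None}
        try:
            outputs = _process_one(str(path), cfg, cfg.outdir)
            entry["outputs"] = {name: {"path": p, "sha256": _sha256(p)}
                                for name, p in outputs.items()}
        except (MammocadError, OSError) as exc:
            log.error("failed on %s: %s", path, exc)
            entry["error"] = f"{type(exc).__name__}: {exc}"
        entries.append(entry)

    manifest = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "n_inputs": len(entries),
        "n_failed": sum(1 for e in entries if e["error"] is not None),
        "files": entries,
    }
    mpath = os.path.join(cfg.outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("manifest written to %s (%d inputs, %d failed)",
             mpath, manifest["n_inputs"], manifest["n_failed"])
    return manifest
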