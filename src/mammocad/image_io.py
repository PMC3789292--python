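"""Reading and writing mammograms.

Mammograms arrive either as DICOM Part-10 files (Modality MG, typically
12–16 bit) or as generic rasters (PNG/JPEG/PGM).  Everything is normalised
into a single in-memory representation, :class:`GrayImage`: a 2D array of
non-negative intensities, row-major, origin at the top-left, 0-based
(row, col) coordinates, with optional physical pixel spacing in mm.

Polarity convention: higher stored value = brighter.  DICOM MONOCHROME1
images are inverted on load so the whole toolkit sees one polarity.
12/16-bit data are kept at native range; any display rescaling happens in
the preprocessing / enhancement modules, never here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from PIL import Image

from .errors import (
    DimensionError,
    InputFormatError,
    MissingPixelDataError,
    ParameterError,
    UnsupportedFormatError,
    WriteError,
)

__all__ = ["GrayImage", "load_image", "save_image"]


@dataclass
class GrayImage:
    """A grayscale raster with optional physical pixel spacing.

    Attributes
    ----------
    pixels : ndarray
        2D array of finite, non-negative intensities.
    spacing_mm : (row_mm, col_mm) or None
        Physical size of one pixel.  Absent when the source carried no
        spacing; physical measurements then refuse rather than assume.
    bit_depth : int
        Sample precision of the source (8 for PNG/JPEG 'L', 12/16 for
        typical DICOM mammograms).  ``max_range`` is ``2**bit_depth - 1``.
    source_id : str
        Free-text provenance (usually the originating path).
    """

    pixels: np.ndarray
    spacing_mm: Optional[Tuple[float, float]] = None
    bit_depth: int = 8
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError(f"pixels must be a 2D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ParameterError("pixel intensities must be finite")
        if px.min() < 0:
            raise ParameterError("pixel intensities must be non-negative")
        if self.bit_depth < 1 or self.bit_depth > 32:
            raise ParameterError(f"bit_depth out of range: {self.bit_depth}")
        if self.spacing_mm is not None:
            r, c = self.spacing_mm
            if not (r > 0 and c > 0):
                raise ParameterError(f"spacing_mm components must be > 0, got {self.spacing_mm}")
            self.spacing_mm = (float(r), float(c))
        self.pixels = px

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_range(self) -> int:
        """Full-scale value of the declared bit depth."""
        return (1 << self.bit_depth) - 1

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=np.float64)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _is_dicom(path: str) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _load_dicom(path: str) -> GrayImage:
    ds = pydicom.dcmread(path)
    if "PixelData" not in ds:
        raise MissingPixelDataError(f"DICOM file has no pixel data: {path}")
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise InputFormatError(f"expected a single-frame grayscale DICOM, got shape {arr.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    bits = int(getattr(ds, "BitsStored", 16))
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        arr = ((1 << bits) - 1) - arr
    arr = np.clip(arr, 0.0, None)
    if float(arr.max(initial=0.0)) == np.floor(float(arr.max(initial=0.0))) and np.all(arr == np.floor(arr)):
        arr = arr.astype(np.int64)
    spacing = None
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None and len(ps) == 2:
        spacing = (float(ps[0]), float(ps[1]))
    elif getattr(ds, "ImagerPixelSpacing", None) is not None:
        ips = ds.ImagerPixelSpacing
        spacing = (float(ips[0]), float(ips[1]))
    return GrayImage(pixels=arr, spacing_mm=spacing, bit_depth=bits, source_id=str(path))


def _load_raster(path: str) -> GrayImage:
    try:
        im = Image.open(path)
        im.load()
    except Exception as exc:  # pillow raises various subclasses
        raise InputFormatError(f"cannot read image file {path}: {exc}") from exc
    if im.mode in ("I;16", "I;16B", "I"):
        arr = np.asarray(im, dtype=np.int64)
        bits = 16
    elif im.mode == "L":
        arr = np.asarray(im, dtype=np.int64)
        bits = 8
    else:
        # multi-channel rasters are converted to luminance
        arr = np.asarray(im.convert("L"), dtype=np.int64)
        bits = 8
    if arr.ndim != 2:
        raise InputFormatError(f"expected a 2D raster, got shape {arr.shape}")
    # plain PGM with maxval > 255 comes through mode I
    if bits == 16 and arr.max(initial=0) <= 255 and path.lower().endswith((".pgm", ".pnm")):
        bits = _pgm_bit_depth(path)
    return GrayImage(pixels=arr, spacing_mm=None, bit_depth=bits, source_id=str(path))


def _pgm_bit_depth(path: str) -> int:
    try:
        with open(path, "rb") as fh:
            head = fh.read(512).split()
        maxval = int(head[3])
        return 8 if maxval <= 255 else 16
    except Exception:
        return 16


def load_image(path: str | os.PathLike) -> GrayImage:
    """Read a mammogram from DICOM, PNG, JPEG or PGM into a :class:`GrayImage`.

    DICOM rescale slope/intercept are applied and pixel spacing is captured
    when present; multi-channel rasters are converted to luminance.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputFormatError(f"no such file: {path}")
    if _is_dicom(path):
        return _load_dicom(path)
    return _load_raster(path)


# ---------------------------------------------------------------------------
# saving
# ---------------------------------------------------------------------------

def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


def _save_dicom(img: GrayImage, path: str) -> None:
    px = _round_half_up(img.pixels)
    if px.max(initial=0) > 65535:
        raise UnsupportedFormatError("DICOM writer supports up to 16-bit samples")
    bits_alloc = 8 if img.bit_depth <= 8 else 16
    arr = px.astype(np.uint8 if bits_alloc == 8 else np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MG"
    ds.PatientName = ""
    ds.PatientID = ""
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = img.rows, img.cols
    ds.BitsAllocated = bits_alloc
    ds.BitsStored = img.bit_depth
    ds.HighBit = img.bit_depth - 1
    ds.PixelRepresentation = 0
    if img.spacing_mm is not None:
        ds.PixelSpacing = [f"{img.spacing_mm[0]:.10g}", f"{img.spacing_mm[1]:.10g}"]
    ds.PixelData = arr.tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def _save_pgm(img: GrayImage, path: str) -> None:
    px = _round_half_up(img.pixels)
    maxval = img.max_range
    if px.max(initial=0) > maxval or maxval > 65535:
        raise UnsupportedFormatError("PGM writer supports samples up to 16 bit within max_range")
    lines = [f"P2", f"{img.cols} {img.rows}", f"{maxval}"]
    for row in px:
        lines.append(" ".join(str(int(v)) for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _save_png(img: GrayImage, path: str) -> None:
    # 8-bit quantization rule: intensities are mapped linearly from
    # [0, max_range] to [0, 255] and rounded half-up.  Identity for 8-bit.
    scale = 255.0 / img.max_range
    px = np.clip(_round_half_up(img.astype_float() * scale), 0, 255).astype(np.uint8)
    Image.fromarray(px, mode="L").save(path, format="PNG")


def save_image(img: GrayImage, path: str | os.PathLike, format: str | None = None) -> str:
    """Write ``img`` to ``path`` in DICOM, PNG or PGM form.

    Lossless round-trip holds for DICOM and PGM on integer images; PNG
    applies the documented 8-bit quantization rule.
    """
    path = os.fspath(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".dcm": "dicom", ".dicom": "dicom", ".png": "png", ".pgm": "pgm"}.get(ext)
        if format is None:
            raise UnsupportedFormatError(f"cannot infer output format from {path!r}")
    format = format.lower()
    writers = {"dicom": _save_dicom, "png": _save_png, "pgm": _save_pgm}
    if format not in writers:
        raise UnsupportedFormatError(f"unsupported output format: {format!r}")
    try:
        writers[format](img, path)
    except OSError as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc
    return path
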