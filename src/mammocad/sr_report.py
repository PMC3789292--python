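"""Structured reporting of CAD findings as DICOM-SR.

A regular mammographic study carries four images — CC and MLO projections
of each breast — and the report mirrors that: study → breast (L/R) →
projection (CC/MLO) → ordered findings.  Each finding records its kind
(mass, microcalcification or distortion), pixel-space location (0-based
row/col; a descriptor item in the document names the convention), optional
physical size in mm, optional closed contour, the algorithm that produced
it, and whether patient-risk context flagged it for emphasis.

Serialization uses a pragmatic CONTAINER/CODE/NUM/SCOORD content tree on a
private coding scheme (no conformance to the Mammography-CAD SR template
family is claimed), written and parsed with pydicom.  ``read_sr`` is the
exact inverse of ``write_sr``; a JSON sidecar mirror of the tree is always
written alongside the DICOM file for diff-friendly inspection.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.sequence import Sequence as DSequence
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import ParameterError, UnsupportedTemplateError, WriteError

__all__ = ["LesionFinding", "ReportTree", "build_report", "write_sr", "read_sr"]

_SCHEME = "99MAMMOCAD"
_COMPREHENSIVE_SR = "1.2.840.10008.5.1.4.1.1.88.33"
_UID_ROOT_ENTROPY = "mammocad-sr"

_KINDS = ("mass", "microcalcification", "distortion")
_LATERALITIES = ("L", "R")
_PROJECTIONS = ("CC", "MLO")


@dataclass
class LesionFinding:
    """One detected or marked lesion."""

    kind: str
    laterality: str
    projection: str
    centroid: Tuple[float, float]            # (row, col), 0-based
    size_mm: Optional[float] = None
    contour: Optional[List[Tuple[float, float]]] = None   # closed: first == last
    source_algorithm: str = ""
    highlight: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.laterality not in _LATERALITIES:
            raise ParameterError(f"laterality must be L or R, got {self.laterality!r}")
        if self.projection not in _PROJECTIONS:
            raise ParameterError(f"projection must be CC or MLO, got {self.projection!r}")
        if self.size_mm is not None and not self.size_mm > 0:
            raise ParameterError(f"size_mm must be > 0, got {self.size_mm}")
        if self.contour is not None:
            if len(self.contour) < 2 or tuple(self.contour[0]) != tuple(self.contour[-1]):
                raise ParameterError("contour must be a closed polyline (first point == last)")
            self.contour = [(float(r), float(c)) for (r, c) in self.contour]
        self.centroid = (float(self.centroid[0]), float(self.centroid[1]))


#: node order of a regular four-image study
_NODES: Tuple[Tuple[str, str], ...] = (("L", "CC"), ("L", "MLO"), ("R", "CC"), ("R", "MLO"))


@dataclass
class ReportTree:
    """study → breast → projection → findings; empty nodes are retained."""

    study_id: str
    patient_ref: str = ""
    created: _dt.datetime = field(default_factory=lambda: _dt.datetime(2000, 1, 1))
    nodes: Dict[Tuple[str, str], List[LesionFinding]] = field(
        default_factory=lambda: {k: [] for k in _NODES})

    def all_findings(self) -> List[LesionFinding]:
        return [f for key in _NODES for f in self.nodes[key]]

    def equals(self, other: "ReportTree", coord_tol: float = 1e-6) -> bool:
        """Field-by-field equality, coordinates compared within ``coord_tol``."""
        if (self.study_id, self.patient_ref) != (other.study_id, other.patient_ref):
            return False
        if abs((self.created - other.created).total_seconds()) > 1.0:
            return False
        for key in _NODES:
            a, b = self.nodes[key], other.nodes[key]
            if len(a) != len(b):
                return False
            for fa, fb in zip(a, b):
                if (fa.kind, fa.laterality, fa.projection, fa.highlight,
                        fa.source_algorithm) != (fb.kind, fb.laterality, fb.projection,
                                                 fb.highlight, fb.source_algorithm):
                    return False
                if any(abs(x - y) > coord_tol for x, y in zip(fa.centroid, fb.centroid)):
                    return False
                if (fa.size_mm is None) != (fb.size_mm is None):
                    return False
                if fa.size_mm is not None and abs(fa.size_mm - fb.size_mm) > coord_tol:
                    return False
                if (fa.contour is None) != (fb.contour is None):
                    return False
                if fa.contour is not None:
                    if len(fa.contour) != len(fb.contour):
                        return False
                    for pa, pb in zip(fa.contour, fb.contour):
                        if abs(pa[0] - pb[0]) > coord_tol or abs(pa[1] - pb[1]) > coord_tol:
                            return False
        return True


def build_report(study_id: str, findings: Sequence[LesionFinding],
                 patient_ref: str = "", created: Optional[_dt.datetime] = None) -> ReportTree:
    """Route findings to their (laterality, projection) node.

    All four image nodes of a regular study exist even when empty.
    """
    tree = ReportTree(study_id=str(study_id), patient_ref=str(patient_ref),
                      created=created or _dt.datetime.now())
    for f in findings:
        tree.nodes[(f.laterality, f.projection)].append(f)
    return tree


# ---------------------------------------------------------------------------
# content-item helpers
# ---------------------------------------------------------------------------

def _code(value: str, meaning: str) -> Dataset:
    d = Dataset()
    d.CodeValue = value[:16]
    d.CodingSchemeDesignator = _SCHEME
    d.CodeMeaning = meaning
    return d


def _container(concept: Dataset, items: List[Dataset]) -> Dataset:
    d = Dataset()
    d.RelationshipType = "CONTAINS"
    d.ValueType = "CONTAINER"
    d.ConceptNameCodeSequence = DSequence([concept])
    d.ContinuityOfContent = "SEPARATE"
    d.ContentSequence = DSequence(items)
    return d


def _text(concept: Dataset, value: str) -> Dataset:
    d = Dataset()
    d.RelationshipType = "CONTAINS"
    d.ValueType = "TEXT"
    d.ConceptNameCodeSequence = DSequence([concept])
    d.TextValue = value if value != "" else " "   # DICOM type 1: never empty
    return d


def _code_item(concept: Dataset, code: Dataset) -> Dataset:
    d = Dataset()
    d.RelationshipType = "CONTAINS"
    d.ValueType = "CODE"
    d.ConceptNameCodeSequence = DSequence([concept])
    d.ConceptCodeSequence = DSequence([code])
    return d


def _num(concept: Dataset, value: float, units: str) -> Dataset:
    d = Dataset()
    d.RelationshipType = "CONTAINS"
    d.ValueType = "NUM"
    d.ConceptNameCodeSequence = DSequence([concept])
    mv = Dataset()
    mv.NumericValue = f"{value:.10g}"
    mv.MeasurementUnitsCodeSequence = DSequence([_code(units, units)])
    d.MeasuredValueSequence = DSequence([mv])
    return d


def _scoord(concept: Dataset, graphic_type: str, points_rc: List[Tuple[float, float]]) -> Dataset:
    d = Dataset()
    d.RelationshipType = "CONTAINS"
    d.ValueType = "SCOORD"
    d.ConceptNameCodeSequence = DSequence([concept])
    d.GraphicType = graphic_type
    flat: List[float] = []
    for (r, c) in points_rc:   # SCOORD graphic data is (column, row) ordered
        flat.extend([float(c), float(r)])
    d.GraphicData = flat
    return d


def _finding_items(f: LesionFinding) -> Dataset:
    items: List[Dataset] = [
        _code_item(_code("KIND", "Finding kind"), _code(f.kind[:16].upper(), f.kind)),
        _scoord(_code("CENTROID", "Finding centroid (0-based row/col)"), "POINT", [f.centroid]),
        _text(_code("ALGORITHM", "Source algorithm"), f.source_algorithm),
        _code_item(_code("HIGHLIGHT", "EHR-guided emphasis"),
                   _code("TRUE" if f.highlight else "FALSE", str(f.highlight).lower())),
    ]
    if f.size_mm is not None:
        items.insert(2, _num(_code("SIZE", "Finding size"), f.size_mm, "mm"))
    if f.contour is not None:
        items.append(_scoord(_code("CONTOUR", "Finding contour (0-based row/col)"),
                             "POLYLINE", f.contour))
    # SCOORD graphic data is single-precision by VR; a JSON TEXT item keeps
    # the coordinates lossless so the round-trip is exact
    items.append(_text(_code("COORDFP", "Full-precision coordinates (JSON)"),
                       json.dumps({"centroid": list(f.centroid),
                                   "contour": [list(p) for p in f.contour]
                                   if f.contour is not None else None})))
    return _container(_code("FINDING", "CAD finding"), items)


def _tree_fingerprint(tree: ReportTree) -> str:
    payload = json.dumps(_tree_to_jsonable(tree), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _tree_to_jsonable(tree: ReportTree) -> dict:
    return {
        "study_id": tree.study_id,
        "patient_ref": tree.patient_ref,
        "created": tree.created.isoformat(),
        "coordinate_convention": "0-based (row, col), origin top-left",
        "nodes": {
            f"{lat}/{proj}": [
                {
                    "kind": f.kind, "laterality": f.laterality, "projection": f.projection,
                    "centroid": list(f.centroid), "size_mm": f.size_mm,
                    "contour": [list(p) for p in f.contour] if f.contour is not None else None,
                    "source_algorithm": f.source_algorithm, "highlight": f.highlight,
                }
                for f in tree.nodes[(lat, proj)]
            ]
            for (lat, proj) in _NODES
        },
    }


def write_sr(tree: ReportTree, path: str | os.PathLike) -> str:
    """Serialize the report as a Comprehensive-SR DICOM file (+ JSON sidecar).

    Instance UIDs are derived from the tree content, so identical trees
    produce byte-identical files.
    """
    path = os.fspath(path)
    fp = _tree_fingerprint(tree)
    sop_uid = generate_uid(entropy_srcs=[_UID_ROOT_ENTROPY, fp, "sop"])

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _COMPREHENSIVE_SR
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _COMPREHENSIVE_SR
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "SR"
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[_UID_ROOT_ENTROPY, fp, "series"])
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[_UID_ROOT_ENTROPY, tree.study_id, "study"])
    ds.PatientID = tree.patient_ref[:64]
    ds.PatientName = ""
    ds.ContentDate = tree.created.strftime("%Y%m%d")
    ds.ContentTime = tree.created.strftime("%H%M%S.%f")
    ds.CompletionFlag = "COMPLETE"
    ds.VerificationFlag = "UNVERIFIED"

    ds.ValueType = "CONTAINER"
    ds.ConceptNameCodeSequence = DSequence([_code("MCADREPORT", "Mammography CAD report")])
    ds.ContinuityOfContent = "SEPARATE"

    root_items: List[Dataset] = [
        _text(_code("STUDYID", "Study identifier"), tree.study_id),
        _text(_code("PATREF", "Patient reference"), tree.patient_ref),
        _text(_code("PIXCONV", "Pixel coordinate convention"),
              "0-based (row, col), origin top-left; SCOORD data ordered (col, row)"),
    ]
    for lat in _LATERALITIES:
        proj_items = []
        for proj in _PROJECTIONS:
            finding_items = [_finding_items(f) for f in tree.nodes[(lat, proj)]]
            proj_items.append(_container(_code(f"PROJ-{proj}", f"{proj} projection"),
                                         finding_items))
        root_items.append(_container(_code(f"BREAST-{lat}", f"Breast {lat}"), proj_items))
    ds.ContentSequence = DSequence(root_items)

    try:
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        with open(path + ".json", "w") as fh:
            json.dump(_tree_to_jsonable(tree), fh, indent=1)
    except OSError as exc:
        raise WriteError(f"cannot write SR to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _concept_value(item: Dataset) -> str:
    seq = getattr(item, "ConceptNameCodeSequence", None)
    if not seq:
        return ""
    return str(seq[0].CodeValue)


def _items_by_value_type(seq, vtype: str):
    return [it for it in (seq or []) if getattr(it, "ValueType", "") == vtype]


def _parse_finding(item: Dataset, lat: str, proj: str) -> LesionFinding:
    kind = size_mm = contour = None
    centroid = (0.0, 0.0)
    algorithm = ""
    highlight = False
    for sub in item.ContentSequence:
        cv = _concept_value(sub)
        if cv == "KIND":
            kind = str(sub.ConceptCodeSequence[0].CodeMeaning)
        elif cv == "CENTROID":
            g = [float(v) for v in sub.GraphicData]
            centroid = (g[1], g[0])
        elif cv == "SIZE":
            size_mm = float(sub.MeasuredValueSequence[0].NumericValue)
        elif cv == "CONTOUR":
            g = [float(v) for v in sub.GraphicData]
            contour = [(g[i + 1], g[i]) for i in range(0, len(g), 2)]
        elif cv == "ALGORITHM":
            algorithm = str(sub.TextValue).strip()
        elif cv == "HIGHLIGHT":
            highlight = str(sub.ConceptCodeSequence[0].CodeValue) == "TRUE"
        elif cv == "COORDFP":
            fp = json.loads(str(sub.TextValue))
            centroid = tuple(fp["centroid"])
            if fp.get("contour") is not None:
                contour = [tuple(p) for p in fp["contour"]]
    if kind is None:
        raise UnsupportedTemplateError("finding container lacks a KIND item")
    return LesionFinding(kind=kind, laterality=lat, projection=proj, centroid=centroid,
                         size_mm=size_mm, contour=contour, source_algorithm=algorithm,
                         highlight=highlight)


def read_sr(path: str | os.PathLike) -> ReportTree:
    """Parse an SR document written by :func:`write_sr` back into a tree.

    A foreign SR layout raises :class:`UnsupportedTemplateError` naming the
    offending concept code.
    """
    ds = pydicom.dcmread(os.fspath(path))
    root_cv = _concept_value(ds)
    if root_cv != "MCADREPORT" or getattr(ds, "ValueType", "") != "CONTAINER":
        raise UnsupportedTemplateError(
            f"not a mammocad SR document: root concept {root_cv!r} "
            f"(expected 'MCADREPORT' in scheme {_SCHEME})")

    study_id = patient_ref = ""
    nodes: Dict[Tuple[str, str], List[LesionFinding]] = {k: [] for k in _NODES}
    for item in ds.ContentSequence:
        cv = _concept_value(item)
        if cv == "STUDYID":
            study_id = str(item.TextValue).strip()
        elif cv == "PATREF":
            patient_ref = str(item.TextValue).strip()
        elif cv.startswith("BREAST-"):
            lat = cv.split("-", 1)[1]
            for proj_item in _items_by_value_type(item.ContentSequence, "CONTAINER"):
                pcv = _concept_value(proj_item)
                if not pcv.startswith("PROJ-"):
                    raise UnsupportedTemplateError(f"unexpected container {pcv!r} under {cv!r}")
                proj = pcv.split("-", 1)[1]
                for f_item in _items_by_value_type(proj_item.ContentSequence, "CONTAINER"):
                    nodes[(lat, proj)].append(_parse_finding(f_item, lat, proj))

    created = _dt.datetime(2000, 1, 1)
    if getattr(ds, "ContentDate", "") and getattr(ds, "ContentTime", ""):
        t = str(ds.ContentTime)
        fmt = "%H%M%S.%f" if "." in t else "%H%M%S"
        created = _dt.datetime.strptime(str(ds.ContentDate) + t, "%Y%m%d" + fmt)

    tree = ReportTree(study_id=study_id, patient_ref=patient_ref, created=created, nodes=nodes)
    return tree
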