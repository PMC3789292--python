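"""Structured reports: tree construction and DICOM-SR round-trips."""

import datetime
import json

import numpy as np
import pydicom
import pytest

from mammocad import LesionFinding, build_report, read_sr, write_sr
from mammocad.errors import ParameterError, UnsupportedTemplateError

KINDS = ("mass", "microcalcification", "distortion")
NODES = (("L", "CC"), ("L", "MLO"), ("R", "CC"), ("R", "MLO"))


def random_tree(rng, n_findings=None):
    n = int(rng.integers(0, 8)) if n_findings is None else n_findings
    findings = []
    for _ in range(n):
        lat, proj = NODES[int(rng.integers(0, 4))]
        contour = None
        if rng.random() < 0.5:
            pts = [(float(r), float(c)) for r, c in rng.uniform(0, 500, (4, 2))]
            contour = pts + [pts[0]]
        findings.append(LesionFinding(
            kind=KINDS[int(rng.integers(0, 3))], laterality=lat, projection=proj,
            centroid=tuple(rng.uniform(0, 4000, 2)),
            size_mm=float(rng.uniform(0.5, 30)) if rng.random() < 0.7 else None,
            contour=contour,
            source_algorithm=["fcm", "bspline", "adaptive"][int(rng.integers(0, 3))],
            highlight=bool(rng.random() < 0.3)))
    created = datetime.datetime(2013, 9, 17) + datetime.timedelta(
        seconds=int(rng.integers(0, 10 ** 7)))
    return build_report(study_id=f"study-{int(rng.integers(1e6))}", findings=findings,
                        patient_ref=f"pat-{int(rng.integers(1e4))}", created=created)


class TestBuildReport:
    def test_empty_study_keeps_four_image_nodes(self):
        tree = build_report("s1", [])
        assert set(tree.nodes) == set(NODES)
        assert all(tree.nodes[k] == [] for k in NODES)

    def test_single_finding_routed_to_its_node(self):
        f = LesionFinding("mass", "L", "CC", (10.0, 20.0))
        tree = build_report("s2", [f])
        assert tree.nodes[("L", "CC")] == [f]
        assert sum(len(v) for v in tree.nodes.values()) == 1

    def test_counts_preserved_across_nodes(self, rng):
        tree = random_tree(rng, n_findings=7)
        assert sum(len(v) for v in tree.nodes.values()) == 7

    def test_invalid_finding_fields_rejected(self):
        with pytest.raises(ParameterError):
            LesionFinding("lump", "L", "CC", (0.0, 0.0))
        with pytest.raises(ParameterError):
            LesionFinding("mass", "L", "CC", (0.0, 0.0), size_mm=0.0)
        with pytest.raises(ParameterError):
            LesionFinding("mass", "L", "CC", (0.0, 0.0),
                          contour=[(0.0, 0.0), (1.0, 1.0)])  # not closed


class TestRoundTrip:
    def test_empty_tree(self, tmp_path):
        tree = build_report("empty", [], created=datetime.datetime(2013, 1, 2, 3, 4, 5))
        path = write_sr(tree, tmp_path / "empty.dcm")
        assert read_sr(path).equals(tree)

    def test_three_findings_field_by_field(self, tmp_path, rng):
        tree = random_tree(rng, n_findings=3)
        back = read_sr(write_sr(tree, tmp_path / "t3.dcm"))
        assert back.equals(tree, coord_tol=1e-6)

    def test_many_randomized_trees(self, tmp_path, rng):
        for i in range(25):
            tree = random_tree(rng)
            back = read_sr(write_sr(tree, tmp_path / f"t{i}.dcm"))
            assert back.equals(tree, coord_tol=1e-6)

    def test_finding_multiset_preserved(self, tmp_path, rng):
        tree = random_tree(rng, n_findings=6)
        back = read_sr(write_sr(tree, tmp_path / "ms.dcm"))
        orig = sorted((f.kind, f.laterality, f.projection) for f in tree.all_findings())
        rt = sorted((f.kind, f.laterality, f.projection) for f in back.all_findings())
        assert orig == rt

    def test_document_is_wellformed_sr(self, tmp_path, rng):
        path = write_sr(random_tree(rng, n_findings=2), tmp_path / "wf.dcm")
        ds = pydicom.dcmread(path)
        assert ds.Modality == "SR"
        assert ds.SOPClassUID == "1.2.840.10008.5.1.4.1.1.88.33"
        assert ds.ValueType == "CONTAINER"
        assert ds.ContentSequence  # non-empty content tree

    def test_sidecar_mirrors_tree(self, tmp_path, rng):
        tree = random_tree(rng, n_findings=2)
        path = write_sr(tree, tmp_path / "sc.dcm")
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        assert sidecar["study_id"] == tree.study_id
        assert sum(len(v) for v in sidecar["nodes"].values()) == 2

    def test_identical_trees_write_identical_bytes(self, tmp_path, rng):
        tree = random_tree(rng, n_findings=4)
        p1 = write_sr(tree, tmp_path / "a.dcm")
        p2 = write_sr(tree, tmp_path / "b.dcm")
        assert open(p1, "rb").read() == open(p2, "rb").read()


def test_foreign_sr_rejected_with_named_code(tmp_path):
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.sequence import Sequence
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.88.33"
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "SR"
    ds.ValueType = "CONTAINER"
    concept = Dataset()
    concept.CodeValue = "111036"
    concept.CodingSchemeDesignator = "DCM"
    concept.CodeMeaning = "Mammography CAD Report"
    ds.ConceptNameCodeSequence = Sequence([concept])
    ds.ContinuityOfContent = "SEPARATE"
    ds.ContentSequence = Sequence([])
    path = tmp_path / "foreign.dcm"
    pydicom.dcmwrite(path, ds, enforce_file_format=True)
    with pytest.raises(UnsupportedTemplateError, match="111036"):
        read_sr(path)
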