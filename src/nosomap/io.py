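"""XML spectra/mask dialect and delimited-table serialization.

The spectra document holds either canonical 512-point spectra, feature
(219-point) spectra, or raw FIDs with acquisition metadata.  All values
round-trip losslessly via ``repr``-precision floats.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from nosomap import grid
from nosomap.synth.fid import FID
from nosomap.synth.phantom import TRUTH_LABELS

FORMAT_VERSION = "1"
REPRESENTATIONS = ("canonical", "feature", "fid")
_REP_LENGTHS = {
    "canonical": grid.N_POINTS,
    "feature": len(grid.CLINICAL_INDICES),
}


class SpectraFormatError(ValueError):
    """Malformed spectra/mask document."""


@dataclass
class SpectraDocument:
    """In-memory form of the spectra XML dialect."""

    representation: str
    records: list[dict[str, Any]]  # id, label, values | fid
    version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise SpectraFormatError(
                f"unknown representation {self.representation!r}"
            )
        seen = set()
        for rec in self.records:
            rid = rec["id"]
            if rid in seen:
                raise SpectraFormatError(f"duplicate identifier {rid!r}")
            seen.add(rid)
            if self.representation in _REP_LENGTHS:
                want = _REP_LENGTHS[self.representation]
                if len(rec["values"]) != want:
                    raise SpectraFormatError(
                        f"record {rid!r} has {len(rec['values'])} values, "
                        f"expected {want}"
                    )

    @property
    def labels(self) -> list[str | None]:
        return [rec.get("label") for rec in self.records]

    def value_matrix(self) -> np.ndarray:
        if self.representation == "fid":
            raise SpectraFormatError("FID documents have no value matrix")
        return np.array([rec["values"] for rec in self.records])

    def fids(self) -> list[FID]:
        if self.representation != "fid":
            raise SpectraFormatError("not a FID document")
        return [rec["fid"] for rec in self.records]


def _fmt(x: float) -> str:
    return repr(float(x))


def _fmt_values(values: np.ndarray) -> str:
    return " ".join(_fmt(v) for v in values)


def spectra_from_fids(
    fids: list[FID],
    labels: "list[str | None] | None" = None,
    ids: "list[str] | None" = None,
) -> SpectraDocument:
    labels = labels or [None] * len(fids)
    ids = ids or [f"v{i:05d}" for i in range(len(fids))]
    records = [
        {"id": rid, "label": lbl, "fid": fid}
        for rid, lbl, fid in zip(ids, labels, fids)
    ]
    return SpectraDocument(representation="fid", records=records)


def spectra_from_matrix(
    matrix: np.ndarray,
    representation: str,
    labels: "list[str | None] | None" = None,
    ids: "list[str] | None" = None,
) -> SpectraDocument:
    matrix = np.asarray(matrix)
    labels = labels or [None] * len(matrix)
    ids = ids or [f"v{i:05d}" for i in range(len(matrix))]
    records = [
        {"id": rid, "label": lbl, "values": row.tolist()}
        for rid, lbl, row in zip(ids, labels, matrix)
    ]
    return SpectraDocument(representation=representation, records=records)


def write_spectra(doc: SpectraDocument, path: str) -> None:
    root = ET.Element(
        "spectra",
        version=doc.version,
        representation=doc.representation,
    )
    for rec in doc.records:
        attrs = {"id": str(rec["id"])}
        if rec.get("label") is not None:
            attrs["label"] = str(rec["label"])
        el = ET.SubElement(root, "record", **attrs)
        if doc.representation == "fid":
            fid: FID = rec["fid"]
            fid_el = ET.SubElement(
                el,
                "fid",
                dwell_time=_fmt(fid.dwell_time),
                transmitter_frequency=_fmt(fid.transmitter_frequency),
                reference_ppm=_fmt(fid.reference_ppm),
            )
            ET.SubElement(fid_el, "real").text = _fmt_values(fid.samples.real)
            ET.SubElement(fid_el, "imag").text = _fmt_values(fid.samples.imag)
        else:
            ET.SubElement(el, "values").text = _fmt_values(
                np.asarray(rec["values"])
            )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def _parse_floats(text: str, context: str) -> list[float]:
    try:
        return [float(t) for t in (text or "").split()]
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric value in {context}") from exc


def read_spectra(path: str) -> SpectraDocument:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SpectraFormatError(f"malformed XML in {path}: {exc}") from exc
    if root.tag != "spectra":
        raise SpectraFormatError(f"expected <spectra> root, got <{root.tag}>")
    representation = root.get("representation")
    records: list[dict[str, Any]] = []
    for el in root.findall("record"):
        rid = el.get("id")
        if rid is None:
            raise SpectraFormatError("record without id")
        rec: dict[str, Any] = {"id": rid, "label": el.get("label")}
        if representation == "fid":
            fid_el = el.find("fid")
            if fid_el is None:
                raise SpectraFormatError(f"record {rid!r} missing <fid>")
            real = _parse_floats(
                fid_el.findtext("real"), f"record {rid!r} real part"
            )
            imag = _parse_floats(
                fid_el.findtext("imag"), f"record {rid!r} imag part"
            )
            if len(real) != len(imag):
                raise SpectraFormatError(
                    f"record {rid!r} real/imag length mismatch"
                )
            rec["fid"] = FID(
                samples=np.array(real) + 1j * np.array(imag),
                dwell_time=float(fid_el.get("dwell_time")),
                transmitter_frequency=float(
                    fid_el.get("transmitter_frequency")
                ),
                reference_ppm=float(fid_el.get("reference_ppm", 4.7)),
            )
        else:
            rec["values"] = _parse_floats(
                el.findtext("values"), f"record {rid!r}"
            )
        records.append(rec)
    return SpectraDocument(
        representation=representation,
        records=records,
        version=root.get("version", FORMAT_VERSION),
    )


@dataclass
class MaskDocument:
    """Ground-truth voxel labels for one phantom/case."""

    dims: tuple[int, int, int]
    labels: list[str]  # flat, (z*ny + y)*nx + x order
    case_class: str

    def __post_init__(self) -> None:
        if len(self.labels) != int(np.prod(self.dims)):
            raise SpectraFormatError(
                f"label count {len(self.labels)} != dims product "
                f"{int(np.prod(self.dims))}"
            )
        for lbl in self.labels:
            if lbl not in TRUTH_LABELS:
                raise SpectraFormatError(f"unknown label token {lbl!r}")


def write_mask(doc: MaskDocument, path: str) -> None:
    nx, ny, nz = doc.dims
    root = ET.Element(
        "mask",
        nx=str(nx),
        ny=str(ny),
        nz=str(nz),
        case_class=doc.case_class,
    )
    for z in range(nz):
        sl = ET.SubElement(root, "slice", z=str(z))
        for y in range(ny):
            start = (z * ny + y) * nx
            ET.SubElement(sl, "row").text = " ".join(
                doc.labels[start : start + nx]
            )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_mask(path: str) -> MaskDocument:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SpectraFormatError(f"malformed XML in {path}: {exc}") from exc
    if root.tag != "mask":
        raise SpectraFormatError(f"expected <mask> root, got <{root.tag}>")
    dims = tuple(int(root.get(a)) for a in ("nx", "ny", "nz"))
    labels: list[str] = []
    for sl in root.findall("slice"):
        for row in sl.findall("row"):
            labels.extend((row.text or "").split())
    return MaskDocument(
        dims=dims, labels=labels, case_class=root.get("case_class")
    )
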