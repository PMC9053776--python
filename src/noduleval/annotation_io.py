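"""Readers, writers and validators for the annotation file formats.

Two interchangeable encodings are supported for ground-truth (reader) and
algorithm-output (vendor) nodule files:

* an XML dialect (one file per study per source) whose structure is published
  as ``schemas/annotation.xsd``;
* a CSV mirror (one row per nodule, any number of studies/sources per file).

Coordinates may arrive either in patient-space millimetres or as
(column, row, slice) indices; index coordinates require the pixel and slice
spacings in the header and are converted on read as ``x = col * px``,
``y = row * py``, ``z = (slice - 1) * sz`` (slice numbers are 1-based).
Everything downstream of this module works in canonical millimetres.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import pandas as pd
from lxml import etree

from .model import (
    COMPOSITIONS,
    Point3D,
    ReaderAnnotation,
    ValidationError,
    VendorDetection,
)

SCHEMA_VERSION = "1.0"

#: Composition synonyms accepted on read (with a warning); the canonical
#: vocabulary is {solid, ground_glass, part_solid}.
COMPOSITION_SYNONYMS = {
    "sub-solid": "part_solid",
    "subsolid": "part_solid",
    "sub_solid": "part_solid",
    "part-solid": "part_solid",
    "part solid": "part_solid",
    "ground-glass": "ground_glass",
    "ground glass": "ground_glass",
    "groundglass": "ground_glass",
}

Record = Union[ReaderAnnotation, VendorDetection]


class ParseError(Exception):
    """The file is not well-formed XML / CSV."""


@dataclass
class AnnotationFileHeader:
    study_id: str
    source_type: str  # "reader" | "vendor"
    source_id: str
    schema_version: str = SCHEMA_VERSION
    pixel_spacing_mm: Optional[Tuple[float, float]] = None
    slice_spacing_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source_type not in ("reader", "vendor"):
            raise ValidationError(f"unknown source type {self.source_type!r}")
        if self.pixel_spacing_mm is not None:
            px, py = self.pixel_spacing_mm
            if px <= 0 or py <= 0:
                raise ValidationError("pixel spacing must be positive")
        if self.slice_spacing_mm is not None and self.slice_spacing_mm <= 0:
            raise ValidationError("slice spacing must be positive")


@dataclass
class ValidationReport:
    """Findings from :func:`validate_schema`; errors block, warnings do not."""

    path: str
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = [f"{self.path}: {'OK' if self.ok else 'INVALID'}"]
        lines += [f"  error: {e}" for e in self.errors]
        lines += [f"  warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def _load_xsd() -> etree.XMLSchema:
    with resources.files("noduleval.schemas").joinpath("annotation.xsd").open("rb") as f:
        return etree.XMLSchema(etree.parse(f))


_XSD_CACHE: Optional[etree.XMLSchema] = None


def _xsd() -> etree.XMLSchema:
    global _XSD_CACHE
    if _XSD_CACHE is None:
        _XSD_CACHE = _load_xsd()
    return _XSD_CACHE


def _fmt(value: float) -> str:
    # repr(float) is the shortest string that round-trips bit-exactly
    return repr(float(value))


def _canonical_composition(token: str, context: str, findings: list) -> Optional[str]:
    token_norm = token.strip()
    if token_norm in COMPOSITIONS:
        return token_norm
    if token_norm.lower() in COMPOSITION_SYNONYMS:
        mapped = COMPOSITION_SYNONYMS[token_norm.lower()]
        warnings.warn(
            f"{context}: composition synonym {token_norm!r} mapped to {mapped!r}"
        )
        return mapped
    findings.append(f"{context}: unknown composition token {token_norm!r}")
    return None


def _parse_center(
    elem, header: AnnotationFileHeader, context: str, findings: list
) -> Optional[Point3D]:
    try:
        x = float(elem.get("x"))
        y = float(elem.get("y"))
        z = float(elem.get("z"))
    except (TypeError, ValueError):
        findings.append(f"{context}: center coordinates missing or non-numeric")
        return None
    units = elem.get("units", "mm")
    if units == "mm":
        return Point3D(x, y, z)
    if units == "index":
        if header.pixel_spacing_mm is None or header.slice_spacing_mm is None:
            findings.append(
                f"{context}: index coordinates require pixel-spacing and "
                f"slice-spacing in the header"
            )
            return None
        px, py = header.pixel_spacing_mm
        return Point3D(x * px, y * py, (z - 1.0) * header.slice_spacing_mm)
    findings.append(f"{context}: unknown coordinate units {units!r}")
    return None


def _child_text(nodule_elem, tag: str) -> Optional[str]:
    child = nodule_elem.find(tag)
    return None if child is None else (child.text or "").strip()


_KNOWN_NODULE_TAGS = {
    "series-number",
    "slice-number",
    "center",
    "axes",
    "solid-component",
    "composition",
    "location",
    "spiculation",
    "calcification",
    "confidence",
    "extensions",
}


def _parse_nodule(
    elem, header: AnnotationFileHeader, findings: list
) -> Optional[Record]:
    nid = elem.get("id") or "<missing id>"
    context = f"nodule {nid}"
    local_findings: list = []

    center = None
    center_elem = elem.find("center")
    if center_elem is None:
        local_findings.append(f"{context}: missing center")
    else:
        center = _parse_center(center_elem, header, context, local_findings)

    def _axis_pair(tag: str):
        pair_elem = elem.find(tag)
        if pair_elem is None:
            return None, None
        try:
            return float(pair_elem.get("long-mm")), float(pair_elem.get("short-mm"))
        except (TypeError, ValueError):
            local_findings.append(f"{context}: <{tag}> needs numeric long-mm/short-mm")
            return None, None

    long_axis, short_axis = _axis_pair("axes")
    solid_long, solid_short = _axis_pair("solid-component")

    composition = None
    comp_text = _child_text(elem, "composition")
    if comp_text is not None:
        composition = _canonical_composition(comp_text, context, local_findings)

    extras = {}
    ext = elem.find("extensions")
    if ext is not None:
        for child in ext:
            extras[child.tag] = (child.text or "").strip()
    for child in elem:
        if child.tag not in _KNOWN_NODULE_TAGS:
            extras[child.tag] = (child.text or "").strip()

    series = _child_text(elem, "series-number")
    slice_no = _child_text(elem, "slice-number")
    spic = _child_text(elem, "spiculation")
    calc_elem = elem.find("calcification")
    confidence = _child_text(elem, "confidence")

    if local_findings:
        findings.extend(local_findings)
        return None

    try:
        if header.source_type == "reader":
            loc = elem.find("location")
            if loc is None or long_axis is None or series is None or slice_no is None:
                raise ValidationError(
                    f"{context}: reader annotations require series/slice numbers, "
                    f"axes and location"
                )
            if composition is None:
                raise ValidationError(f"{context}: reader annotations require a composition")
            return ReaderAnnotation(
                study_id=header.study_id,
                reader_id=header.source_id,
                annotation_id=nid,
                series_number=int(series),
                slice_number=int(slice_no),
                center=center,
                long_axis_mm=long_axis,
                short_axis_mm=short_axis,
                solid_long_axis_mm=solid_long,
                solid_short_axis_mm=solid_short,
                composition=composition,
                lobar_location=loc.get("lobe"),
                laterality=loc.get("laterality"),
                spiculated=(spic == "true"),
                diffusely_calcified=(
                    calc_elem is not None and calc_elem.get("diffuse") == "true"
                ),
                extras=extras,
            )
        conf_value = float(confidence) if confidence is not None else None
        if conf_value is not None and not (0.0 <= conf_value <= 1.0):
            raise ValidationError(
                f"{context}: confidence {conf_value} outside [0, 1]"
            )
        return VendorDetection(
            study_id=header.study_id,
            vendor_id=header.source_id,
            detection_id=nid,
            center=center,
            long_axis_mm=long_axis,
            short_axis_mm=short_axis,
            predicted_composition=composition,
            confidence=conf_value,
            series_number=int(series) if series is not None else None,
            slice_number=int(slice_no) if slice_no is not None else None,
            extras=extras,
        )
    except (ValidationError, TypeError, ValueError) as exc:
        findings.append(f"{context}: {exc}")
        return None


def _parse_header(root) -> AnnotationFileHeader:
    header_elem = root.find("header")
    if header_elem is None:
        raise ValidationError("missing <header>")
    study = _child_text(header_elem, "study-id")
    source = header_elem.find("source")
    if study is None or source is None:
        raise ValidationError("header requires <study-id> and <source>")
    pixel = header_elem.find("pixel-spacing")
    pixel_spacing = (
        (float(pixel.get("x-mm")), float(pixel.get("y-mm"))) if pixel is not None else None
    )
    slice_elem = header_elem.find("slice-spacing")
    slice_spacing = float(slice_elem.get("mm")) if slice_elem is not None else None
    return AnnotationFileHeader(
        study_id=study,
        source_type=source.get("type"),
        source_id=source.get("id"),
        schema_version=root.get("schema-version", SCHEMA_VERSION),
        pixel_spacing_mm=pixel_spacing,
        slice_spacing_mm=slice_spacing,
    )


def read_annotations(path) -> Tuple[AnnotationFileHeader, List[Record]]:
    """Read and validate one XML annotation file.

    Returns canonical-mm records; raises :class:`ParseError` on malformed XML
    and :class:`ValidationError` (listing every offending nodule) on schema
    violations.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    root = tree.getroot()
    header = _parse_header(root)
    findings: list = []
    records: List[Record] = []
    nodules = root.find("nodules")
    for elem in (nodules if nodules is not None else []):
        if elem.tag != "nodule":
            continue
        record = _parse_nodule(elem, header, findings)
        if record is not None:
            records.append(record)
    if findings:
        raise ValidationError(f"{path}: " + "; ".join(findings))
    return header, records


def _nodule_element(record: Record) -> etree._Element:
    if isinstance(record, ReaderAnnotation):
        nid = record.annotation_id
    else:
        nid = record.detection_id
    elem = etree.Element("nodule", id=nid)
    if getattr(record, "series_number", None) is not None:
        etree.SubElement(elem, "series-number").text = str(record.series_number)
    if getattr(record, "slice_number", None) is not None:
        etree.SubElement(elem, "slice-number").text = str(record.slice_number)
    c = record.center
    etree.SubElement(
        elem, "center", x=_fmt(c.x_mm), y=_fmt(c.y_mm), z=_fmt(c.z_mm), units="mm"
    )
    if record.long_axis_mm is not None:
        etree.SubElement(
            elem,
            "axes",
            **{"long-mm": _fmt(record.long_axis_mm), "short-mm": _fmt(record.short_axis_mm)},
        )
    if isinstance(record, ReaderAnnotation):
        if record.solid_long_axis_mm is not None:
            etree.SubElement(
                elem,
                "solid-component",
                **{
                    "long-mm": _fmt(record.solid_long_axis_mm),
                    "short-mm": _fmt(record.solid_short_axis_mm),
                },
            )
        etree.SubElement(elem, "composition").text = record.composition
        etree.SubElement(
            elem, "location", lobe=record.lobar_location, laterality=record.laterality
        )
        etree.SubElement(elem, "spiculation").text = (
            "true" if record.spiculated else "false"
        )
        etree.SubElement(
            elem,
            "calcification",
            diffuse="true" if record.diffusely_calcified else "false",
        )
    else:
        if record.predicted_composition is not None:
            etree.SubElement(elem, "composition").text = record.predicted_composition
        if record.confidence is not None:
            etree.SubElement(elem, "confidence").text = _fmt(record.confidence)
    if record.extras:
        ext = etree.SubElement(elem, "extensions")
        for tag in sorted(record.extras):
            etree.SubElement(ext, tag).text = str(record.extras[tag])
    return elem


def write_annotations(
    header: AnnotationFileHeader, records: Sequence[Record], path
) -> None:
    """Write one XML annotation file (deterministic: sorted by nodule id)."""
    root = etree.Element("annotation-file", **{"schema-version": SCHEMA_VERSION})
    header_elem = etree.SubElement(root, "header")
    etree.SubElement(header_elem, "study-id").text = header.study_id
    etree.SubElement(
        header_elem, "source", type=header.source_type, id=header.source_id
    )
    if header.pixel_spacing_mm is not None:
        etree.SubElement(
            header_elem,
            "pixel-spacing",
            **{
                "x-mm": _fmt(header.pixel_spacing_mm[0]),
                "y-mm": _fmt(header.pixel_spacing_mm[1]),
            },
        )
    if header.slice_spacing_mm is not None:
        etree.SubElement(
            header_elem, "slice-spacing", mm=_fmt(header.slice_spacing_mm)
        )
    nodules = etree.SubElement(root, "nodules")

    def _record_id(r: Record) -> str:
        return r.annotation_id if isinstance(r, ReaderAnnotation) else r.detection_id

    for record in sorted(records, key=_record_id):
        if record.study_id != header.study_id:
            raise ValidationError(
                f"record {_record_id(record)} belongs to study {record.study_id}, "
                f"file header says {header.study_id}"
            )
        nodules.append(_nodule_element(record))
    Path(path).write_bytes(
        etree.tostring(
            root, xml_declaration=True, encoding="UTF-8", pretty_print=True
        )
    )


def validate_schema(path) -> ValidationReport:
    """Validate one file against the XSD and the semantic rules.

    Never raises for data problems: findings are returned as a report (for
    the CLI's 0 / nonzero exit-code contract).
    """
    report = ValidationReport(path=str(path))
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        report.errors.append(f"not parseable: {exc}")
        return report
    xsd = _xsd()
    if not xsd.validate(tree):
        for entry in xsd.error_log:
            report.errors.append(f"line {entry.line}: {entry.message}")
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            read_annotations(path)
        for w in caught:
            report.warnings.append(str(w.message))
    except (ParseError, ValidationError) as exc:
        report.errors.append(str(exc))
    return report


# ---------------------------------------------------------------------------
# CSV mirror format

CSV_COLUMNS = [
    "study_id",
    "source_type",
    "source_id",
    "nodule_id",
    "series_number",
    "slice_number",
    "x_mm",
    "y_mm",
    "z_mm",
    "long_axis_mm",
    "short_axis_mm",
    "solid_long_axis_mm",
    "solid_short_axis_mm",
    "composition",
    "lobe",
    "laterality",
    "spiculated",
    "diffusely_calcified",
    "confidence",
]


def _record_row(record: Record) -> dict:
    if isinstance(record, ReaderAnnotation):
        return {
            "study_id": record.study_id,
            "source_type": "reader",
            "source_id": record.reader_id,
            "nodule_id": record.annotation_id,
            "series_number": record.series_number,
            "slice_number": record.slice_number,
            "x_mm": record.center.x_mm,
            "y_mm": record.center.y_mm,
            "z_mm": record.center.z_mm,
            "long_axis_mm": record.long_axis_mm,
            "short_axis_mm": record.short_axis_mm,
            "solid_long_axis_mm": record.solid_long_axis_mm,
            "solid_short_axis_mm": record.solid_short_axis_mm,
            "composition": record.composition,
            "lobe": record.lobar_location,
            "laterality": record.laterality,
            "spiculated": record.spiculated,
            "diffusely_calcified": record.diffusely_calcified,
            "confidence": None,
        }
    return {
        "study_id": record.study_id,
        "source_type": "vendor",
        "source_id": record.vendor_id,
        "nodule_id": record.detection_id,
        "series_number": record.series_number,
        "slice_number": record.slice_number,
        "x_mm": record.center.x_mm,
        "y_mm": record.center.y_mm,
        "z_mm": record.center.z_mm,
        "long_axis_mm": record.long_axis_mm,
        "short_axis_mm": record.short_axis_mm,
        "solid_long_axis_mm": None,
        "solid_short_axis_mm": None,
        "composition": record.predicted_composition,
        "lobe": None,
        "laterality": None,
        "spiculated": None,
        "diffusely_calcified": None,
        "confidence": record.confidence,
    }


def write_annotations_csv(records: Sequence[Record], path) -> None:
    """Write the CSV mirror (any mix of studies and sources, sorted rows)."""
    rows = [_record_row(r) for r in records]
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame = frame.sort_values(["study_id", "source_type", "source_id", "nodule_id"])
    frame.to_csv(path, index=False)


def read_annotations_csv(path) -> List[Record]:
    """Read the CSV mirror back into canonical records."""
    frame = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing CSV columns {sorted(missing)}")
    findings: list = []
    records: List[Record] = []

    def _opt(value):
        return None if pd.isna(value) else float(value)

    for _, row in frame.iterrows():
        context = f"nodule {row['nodule_id']}"
        center = Point3D(float(row.x_mm), float(row.y_mm), float(row.z_mm))
        try:
            if row.source_type == "reader":
                composition = _canonical_composition(
                    str(row.composition), context, findings
                )
                if composition is None:
                    continue
                records.append(
                    ReaderAnnotation(
                        study_id=str(row.study_id),
                        reader_id=str(row.source_id),
                        annotation_id=str(row.nodule_id),
                        series_number=int(row.series_number),
                        slice_number=int(row.slice_number),
                        center=center,
                        long_axis_mm=float(row.long_axis_mm),
                        short_axis_mm=float(row.short_axis_mm),
                        solid_long_axis_mm=_opt(row.solid_long_axis_mm),
                        solid_short_axis_mm=_opt(row.solid_short_axis_mm),
                        composition=composition,
                        lobar_location=str(row.lobe),
                        laterality=str(row.laterality),
                        spiculated=bool(row.spiculated),
                        diffusely_calcified=bool(row.diffusely_calcified),
                    )
                )
            else:
                composition = None
                if not pd.isna(row.composition):
                    composition = _canonical_composition(
                        str(row.composition), context, findings
                    )
                records.append(
                    VendorDetection(
                        study_id=str(row.study_id),
                        vendor_id=str(row.source_id),
                        detection_id=str(row.nodule_id),
                        center=center,
                        long_axis_mm=_opt(row.long_axis_mm),
                        short_axis_mm=_opt(row.short_axis_mm),
                        predicted_composition=composition,
                        confidence=_opt(row.confidence),
                    )
                )
        except ValidationError as exc:
            findings.append(str(exc))
    if findings:
        raise ValidationError(f"{path}: " + "; ".join(findings))
    return records
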