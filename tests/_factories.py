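"""Small record factories shared across test modules."""
from noduleval.model import (
    ConsensusNodule,
    Point3D,
    ReaderAnnotation,
    VendorDetection,
)


def annotation(
    x=0.0,
    y=0.0,
    z=0.0,
    reader="R1",
    study="S1",
    aid=None,
    long_axis=8.0,
    short_axis=6.0,
    composition="solid",
    lobe="RUL",
    laterality="right",
    spiculated=False,
    calcified=False,
    solid_long=None,
    solid_short=None,
):
    return ReaderAnnotation(
        study_id=study,
        reader_id=reader,
        annotation_id=aid or f"{reader}-{x}-{y}-{z}",
        series_number=1,
        slice_number=5,
        center=Point3D(x, y, z),
        long_axis_mm=long_axis,
        short_axis_mm=short_axis,
        solid_long_axis_mm=solid_long,
        solid_short_axis_mm=solid_short,
        composition=composition,
        lobar_location=lobe,
        laterality=laterality,
        spiculated=spiculated,
        diffusely_calcified=calcified,
    )


def nodule(
    x=0.0,
    y=0.0,
    z=0.0,
    nid="N1",
    study="S1",
    avg=10.0,
    composition="solid",
    eligibility="eligible",
    readers=("R1", "R2"),
):
    return ConsensusNodule(
        nodule_id=nid,
        study_id=study,
        center=Point3D(x, y, z),
        avg_diameter_mm=avg,
        composition=composition,
        lobar_location="RUL",
        laterality="right",
        spiculated=False,
        supporting_reader_ids=frozenset(readers),
        eligibility=eligibility,
    )


def detection(
    x=0.0,
    y=0.0,
    z=0.0,
    did="D1",
    study="S1",
    vendor="V1",
    long_axis=10.0,
    short_axis=10.0,
    composition=None,
    confidence=None,
):
    return VendorDetection(
        study_id=study,
        vendor_id=vendor,
        detection_id=did,
        center=Point3D(x, y, z),
        long_axis_mm=long_axis,
        short_axis_mm=short_axis,
        predicted_composition=composition,
        confidence=confidence,
    )
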