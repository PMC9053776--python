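"""Core domain model: annotation records, evaluation configuration, and the
3D geometry behind the hit criterion.

All coordinates are patient-space millimetres. Index-based coordinates
(column, row, slice) are converted at ingest by :mod:`noduleval.annotation_io`
using the pixel/slice spacing carried in the file header, so every object in
this module lives in one metric space.

The hit criterion used throughout (reader-to-reader correspondence and
vendor-to-ground-truth matching) has two clauses:

1. the two centers are within ``hit_distance_mm`` (default 10 mm), checked
   per axis by default (each of |dx|, |dy|, |dz| <= 10 mm) or, optionally,
   on the Euclidean norm;
2. the two annotation boxes overlap or touch (closed intervals on every
   axis).

Both clauses use inclusive thresholds: boundary cases count as hits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import FrozenSet, Mapping, Optional

COMPOSITIONS = ("solid", "ground_glass", "part_solid")
LOBES = ("RUL", "RML", "RLL", "LUL", "LLL", "lingula")
LATERALITIES = ("left", "right")
ELIGIBILITIES = ("eligible", "ignored_calcified", "ignored_size")

#: Tie-break precedence for composition votes (two-reader consensus ties):
#: the rarer, clinically stricter class wins and the nodule is flagged.
COMPOSITION_PRECEDENCE = {"part_solid": 0, "ground_glass": 1, "solid": 2}


class ValidationError(ValueError):
    """An annotation, detection or configuration violates a model invariant."""


def _require_finite(context: str, **named: object) -> None:
    for name, value in named.items():
        if not isinstance(value, (int, float)) or not math.isfinite(value):
            raise ValidationError(f"{context}: {name} must be finite, got {value!r}")


@dataclass(frozen=True)
class Point3D:
    """A location in patient space, in millimetres."""

    x_mm: float
    y_mm: float
    z_mm: float

    def __post_init__(self) -> None:
        _require_finite("Point3D", x_mm=self.x_mm, y_mm=self.y_mm, z_mm=self.z_mm)

    def distance_to(self, other: "Point3D") -> float:
        """Euclidean distance in mm."""
        return math.dist(
            (self.x_mm, self.y_mm, self.z_mm), (other.x_mm, other.y_mm, other.z_mm)
        )

    def as_tuple(self) -> tuple:
        return (self.x_mm, self.y_mm, self.z_mm)


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned box in patient space (closed on every face)."""

    min_corner: Point3D
    max_corner: Point3D

    def __post_init__(self) -> None:
        lo, hi = self.min_corner, self.max_corner
        if lo.x_mm > hi.x_mm or lo.y_mm > hi.y_mm or lo.z_mm > hi.z_mm:
            raise ValidationError(
                f"Box3D: min corner must be <= max corner on every axis "
                f"({lo.as_tuple()} vs {hi.as_tuple()})"
            )


@dataclass
class ReaderAnnotation:
    """One radiologist's markup of one nodule.

    ``solid_long_axis_mm``/``solid_short_axis_mm`` carry the separate solid
    component measurement and are present exactly when the composition is
    ``part_solid``.
    """

    study_id: str
    reader_id: str
    annotation_id: str
    series_number: int
    slice_number: int
    center: Point3D
    long_axis_mm: float
    short_axis_mm: float
    composition: str
    lobar_location: str
    laterality: str
    spiculated: bool
    diffusely_calcified: bool = False
    solid_long_axis_mm: Optional[float] = None
    solid_short_axis_mm: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.composition not in COMPOSITIONS:
            raise ValidationError(
                f"{self.annotation_id}: unknown composition {self.composition!r}"
            )
        if self.lobar_location not in LOBES:
            raise ValidationError(
                f"{self.annotation_id}: unknown lobar location {self.lobar_location!r}"
            )
        if self.laterality not in LATERALITIES:
            raise ValidationError(
                f"{self.annotation_id}: unknown laterality {self.laterality!r}"
            )
        _require_finite(
            self.annotation_id,
            long_axis_mm=self.long_axis_mm,
            short_axis_mm=self.short_axis_mm,
        )
        if not (self.long_axis_mm >= self.short_axis_mm > 0):
            raise ValidationError(
                f"{self.annotation_id}: need long_axis >= short_axis > 0, got "
                f"{self.long_axis_mm} / {self.short_axis_mm}"
            )
        has_solid = (
            self.solid_long_axis_mm is not None or self.solid_short_axis_mm is not None
        )
        if self.composition == "part_solid":
            if self.solid_long_axis_mm is None or self.solid_short_axis_mm is None:
                raise ValidationError(
                    f"{self.annotation_id}: part-solid nodules require the solid "
                    f"component measurement"
                )
            if not (self.solid_long_axis_mm >= self.solid_short_axis_mm > 0):
                raise ValidationError(
                    f"{self.annotation_id}: solid component axes must satisfy "
                    f"long >= short > 0"
                )
            if (
                self.solid_long_axis_mm > self.long_axis_mm
                or self.solid_short_axis_mm > self.short_axis_mm
            ):
                raise ValidationError(
                    f"{self.annotation_id}: solid component cannot exceed the "
                    f"whole nodule"
                )
        elif has_solid:
            raise ValidationError(
                f"{self.annotation_id}: solid component measurement only valid "
                f"for part-solid nodules"
            )

    @property
    def avg_diameter_mm(self) -> float:
        return (self.long_axis_mm + self.short_axis_mm) / 2.0


@dataclass
class VendorDetection:
    """One algorithm-output nodule."""

    study_id: str
    vendor_id: str
    detection_id: str
    center: Point3D
    long_axis_mm: Optional[float] = None
    short_axis_mm: Optional[float] = None
    predicted_composition: Optional[str] = None
    confidence: Optional[float] = None
    series_number: Optional[int] = None
    slice_number: Optional[int] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.long_axis_mm is None) != (self.short_axis_mm is None):
            raise ValidationError(
                f"{self.detection_id}: long and short axes must be given together"
            )
        if self.long_axis_mm is not None:
            _require_finite(
                self.detection_id,
                long_axis_mm=self.long_axis_mm,
                short_axis_mm=self.short_axis_mm,
            )
            if not (self.long_axis_mm >= self.short_axis_mm > 0):
                raise ValidationError(
                    f"{self.detection_id}: need long_axis >= short_axis > 0"
                )
        if self.predicted_composition is not None and (
            self.predicted_composition not in COMPOSITIONS
        ):
            raise ValidationError(
                f"{self.detection_id}: unknown composition "
                f"{self.predicted_composition!r}"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"{self.detection_id}: confidence {self.confidence} outside [0, 1]"
            )

    @property
    def avg_diameter_mm(self) -> Optional[float]:
        if self.long_axis_mm is None:
            return None
        return (self.long_axis_mm + self.short_axis_mm) / 2.0


@dataclass
class ConsensusNodule:
    """Majority-accepted ground-truth nodule with aggregated attributes."""

    nodule_id: str
    study_id: str
    center: Point3D
    avg_diameter_mm: float
    composition: str
    lobar_location: str
    laterality: str
    spiculated: bool
    supporting_reader_ids: FrozenSet[str]
    eligibility: str
    composition_tie: bool = False

    def __post_init__(self) -> None:
        if self.composition not in COMPOSITIONS:
            raise ValidationError(f"{self.nodule_id}: unknown composition")
        if self.eligibility not in ELIGIBILITIES:
            raise ValidationError(
                f"{self.nodule_id}: unknown eligibility {self.eligibility!r}"
            )
        if len(self.supporting_reader_ids) < 1:
            raise ValidationError(f"{self.nodule_id}: no supporting readers")
        _require_finite(self.nodule_id, avg_diameter_mm=self.avg_diameter_mm)
        if self.avg_diameter_mm <= 0:
            raise ValidationError(f"{self.nodule_id}: non-positive diameter")


@dataclass
class EvalConfig:
    """Every threshold of the evaluation protocol, in one auditable place.

    Defaults encode the protocol: a detection corresponds to a ground-truth
    nodule when their centers are within 10 mm in each of the three
    dimensions and their annotations overlap or intersect; ground truth
    requires agreement of at least 2 of 3 readers; eligible nodules measure
    between 4 and 30 mm average diameter.
    """

    hit_distance_mm: float = 10.0
    require_overlap: bool = True
    distance_mode: str = "per_axis"  # or "euclidean"
    min_diameter_mm: float = 4.0
    max_diameter_mm: float = 30.0
    min_supporting_readers: int = 2
    duplicate_policy: str = "fp"  # or "ignore"
    count_out_of_range_hits_as_fp: bool = False
    rounding_decimals: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hit_distance_mm <= 0:
            raise ValidationError("hit_distance_mm must be positive")
        if self.distance_mode not in ("per_axis", "euclidean"):
            raise ValidationError(f"unknown distance_mode {self.distance_mode!r}")
        if not (0 < self.min_diameter_mm <= self.max_diameter_mm):
            raise ValidationError("need 0 < min_diameter_mm <= max_diameter_mm")
        if self.min_supporting_readers < 1:
            raise ValidationError("min_supporting_readers must be >= 1")
        if self.duplicate_policy not in ("fp", "ignore"):
            raise ValidationError(f"unknown duplicate_policy {self.duplicate_policy!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "EvalConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))


def within_hit_distance(a: Point3D, b: Point3D, config: EvalConfig) -> bool:
    """Centers-proximity clause of the hit criterion (inclusive threshold)."""
    d = config.hit_distance_mm
    if config.distance_mode == "per_axis":
        return (
            abs(a.x_mm - b.x_mm) <= d
            and abs(a.y_mm - b.y_mm) <= d
            and abs(a.z_mm - b.z_mm) <= d
        )
    return a.distance_to(b) <= d


def annotation_box(obj) -> Box3D:
    """Axis-aligned box realizing an annotation's spatial extent.

    For records carrying a bi-directional measurement the box spans the long
    axis in x and y and the average diameter in z (the schema records no
    per-slice extent, so the through-plane span assumes a roughly isotropic
    lesion). Consensus nodules, which keep only the average diameter, get a
    cube of that side.
    """
    center = obj.center
    long_axis = getattr(obj, "long_axis_mm", None)
    if long_axis is not None:
        half_xy = long_axis / 2.0
        half_z = obj.avg_diameter_mm / 2.0
    else:
        avg = getattr(obj, "avg_diameter_mm", None)
        if avg is None:
            raise ValidationError(
                f"cannot derive a box: no axes on {type(obj).__name__}"
            )
        half_xy = half_z = avg / 2.0
    return Box3D(
        Point3D(center.x_mm - half_xy, center.y_mm - half_xy, center.z_mm - half_z),
        Point3D(center.x_mm + half_xy, center.y_mm + half_xy, center.z_mm + half_z),
    )


def boxes_intersect(a: Box3D, b: Box3D) -> bool:
    """Closed-interval overlap on all three axes (touching faces count)."""
    return (
        a.min_corner.x_mm <= b.max_corner.x_mm
        and b.min_corner.x_mm <= a.max_corner.x_mm
        and a.min_corner.y_mm <= b.max_corner.y_mm
        and b.min_corner.y_mm <= a.max_corner.y_mm
        and a.min_corner.z_mm <= b.max_corner.z_mm
        and b.min_corner.z_mm <= a.max_corner.z_mm
    )


def annotations_correspond(a, b, config: EvalConfig) -> bool:
    """Full hit criterion between two annotation-like records.

    Used both for inter-reader correspondence (consensus clustering) and for
    vendor-to-ground-truth matching; the protocol defines a single proximity
    notion.
    """
    if not within_hit_distance(a.center, b.center, config):
        return False
    if config.require_overlap:
        return boxes_intersect(annotation_box(a), annotation_box(b))
    return True
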