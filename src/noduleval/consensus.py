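"""Fuse multiple readers' annotations into majority-accepted ground truth.

Correspondence between readers uses the same hit criterion as
vendor-to-ground-truth matching (center proximity plus annotation-box
overlap); annotations of one study form a graph whose connected components
are candidate lesions. Components supported by at least
``min_supporting_readers`` distinct readers (default 2 of 3) become
consensus nodules; the rest are dropped.

Aggregation over a component's members: centroid center, mean of the
members' average diameters, majority vote on composition / location /
spiculation. A composition tie (possible with two supporting readers) is
resolved by the precedence part_solid > ground_glass > solid and flagged so
it can be re-adjudicated. Any diffuse-calcification flag marks the nodule
``ignored_calcified`` (conservative: vendors were told not to detect these,
so a possibly-calcified lesion must not count against them); otherwise an
average diameter outside the eligible size window marks it ``ignored_size``.
Ignored nodules are retained — they mask detections during matching but are
excluded from the statistics.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import mean
from typing import List, Sequence, Tuple

from .model import (
    COMPOSITION_PRECEDENCE,
    ConsensusNodule,
    EvalConfig,
    Point3D,
    ReaderAnnotation,
    ValidationError,
    annotations_correspond,
)

#: roundoff guard on the inclusive size window: a diameter reconstructed
#: from long/short axes can miss an exact bound by a few ulps
_SIZE_TOL_MM = 1e-9


@dataclass
class AnnotationCluster:
    component_id: int
    members: List[ReaderAnnotation]

    @property
    def distinct_readers(self) -> frozenset:
        return frozenset(a.reader_id for a in self.members)

    @property
    def has_intra_reader_link(self) -> bool:
        """True when one reader contributed more than one annotation — two
        genuinely distinct lesions cross-linked through other readers."""
        counts = Counter(a.reader_id for a in self.members)
        return any(n > 1 for n in counts.values())


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_annotations(
    annotations: Sequence[ReaderAnnotation], config: EvalConfig
) -> List[AnnotationCluster]:
    """Connected components of the inter-reader correspondence graph.

    Edges join annotations from *different* readers satisfying the hit
    criterion; correspondence is transitive through the component. Component
    ids are deterministic: sorted by the minimal member coordinate tuple.
    """
    annotations = list(annotations)
    if not annotations:
        return []
    studies = {a.study_id for a in annotations}
    if len(studies) > 1:
        raise ValidationError(f"annotations span multiple studies: {sorted(studies)}")
    uf = _UnionFind(len(annotations))
    for i in range(len(annotations)):
        for j in range(i + 1, len(annotations)):
            a, b = annotations[i], annotations[j]
            if a.reader_id == b.reader_id:
                continue
            if annotations_correspond(a, b, config):
                uf.union(i, j)
    groups: dict = {}
    for idx in range(len(annotations)):
        groups.setdefault(uf.find(idx), []).append(annotations[idx])
    ordered = sorted(
        groups.values(),
        key=lambda members: min(m.center.as_tuple() for m in members),
    )
    return [AnnotationCluster(cid, members) for cid, members in enumerate(ordered)]


def _majority(values, tie_breaker=None):
    """Most common value; ties resolved by ``tie_breaker`` ordering (smaller
    wins) or by sorted order for determinism. Returns (winner, was_tie)."""
    counts = Counter(values)
    top = max(counts.values())
    winners = sorted(
        (v for v, n in counts.items() if n == top),
        key=tie_breaker if tie_breaker is not None else (lambda v: v),
    )
    return winners[0], len(winners) > 1


def build_consensus(
    clusters: Sequence[AnnotationCluster],
    config: EvalConfig,
) -> Tuple[List[ConsensusNodule], List[ConsensusNodule]]:
    """Turn clusters into (eligible, ignored) consensus nodules."""
    eligible: List[ConsensusNodule] = []
    ignored: List[ConsensusNodule] = []
    counter = 0
    for cluster in clusters:
        readers = cluster.distinct_readers
        if len(readers) < config.min_supporting_readers:
            continue
        counter += 1
        members = cluster.members
        study_id = members[0].study_id
        center = Point3D(
            mean(m.center.x_mm for m in members),
            mean(m.center.y_mm for m in members),
            mean(m.center.z_mm for m in members),
        )
        avg_diameter = mean(m.avg_diameter_mm for m in members)
        composition, comp_tie = _majority(
            (m.composition for m in members),
            tie_breaker=lambda c: COMPOSITION_PRECEDENCE[c],
        )
        lobe, _ = _majority(m.lobar_location for m in members)
        laterality, _ = _majority(m.laterality for m in members)
        spiculation_votes = Counter(m.spiculated for m in members)
        # boolean tie -> spiculated (conservative, the rarer positive call)
        spiculated = spiculation_votes[True] >= spiculation_votes[False]
        if any(m.diffusely_calcified for m in members):
            status = "ignored_calcified"
        elif not (
            config.min_diameter_mm - _SIZE_TOL_MM
            <= avg_diameter
            <= config.max_diameter_mm + _SIZE_TOL_MM
        ):
            status = "ignored_size"
        else:
            status = "eligible"
        nodule = ConsensusNodule(
            nodule_id=f"{study_id}-N{counter:03d}",
            study_id=study_id,
            center=center,
            avg_diameter_mm=avg_diameter,
            composition=composition,
            lobar_location=lobe,
            laterality=laterality,
            spiculated=spiculated,
            supporting_reader_ids=readers,
            eligibility=status,
            composition_tie=comp_tie,
        )
        (eligible if status == "eligible" else ignored).append(nodule)
    return eligible, ignored


def consensus_for_study(
    annotations: Sequence[ReaderAnnotation], config: EvalConfig
) -> Tuple[List[ConsensusNodule], List[ConsensusNodule]]:
    """Convenience: cluster then build consensus for one study."""
    return build_consensus(cluster_annotations(annotations, config), config)
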