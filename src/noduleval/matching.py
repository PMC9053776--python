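"""Assign vendor detections to consensus ground truth, one study at a time.

The assignment is a maximum-cardinality one-to-one matching on the bipartite
hit graph (a detection can pair with a nodule only when the hit criterion
holds), with ties among maximum matchings broken by minimal total center
distance and then by (detection_id, nodule_id) lexicographic order. This is
deterministic, order-independent, and the most favourable feasible reading
for a vendor; a brute-force enumerator in the test suite serves as its
oracle on small instances.

Label semantics per detection:

* ``TP`` — paired with an eligible consensus nodule;
* ``duplicate`` — unmatched but hitting an already-matched nodule (counted
  as a false positive under the default ``duplicate_policy="fp"``);
* ``ignored_calcified_hit`` — hits a diffusely calcified (masked) nodule;
  removed from all accounting first;
* ``ignored_out_of_range_hit`` — hits a size-ineligible consensus nodule;
  excluded from false positives by default (sub-window lesions were
  deliberately unannotated), reversible via
  ``count_out_of_range_hits_as_fp``;
* ``FP`` — everything else.

Eligible nodules are ``detected`` or ``missed`` (missed = false negative).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import (
    ConsensusNodule,
    EvalConfig,
    ValidationError,
    VendorDetection,
    annotations_correspond,
)

_NON_HIT_COST = 1.0e9
_LEX_EPSILON = 1.0e-9


def is_hit(
    detection: VendorDetection, nodule: ConsensusNodule, config: EvalConfig
) -> bool:
    """Hit criterion between a detection and a consensus nodule."""
    if detection.study_id != nodule.study_id:
        raise ValidationError(
            f"{detection.detection_id} and {nodule.nodule_id} are from "
            f"different studies"
        )
    return annotations_correspond(detection, nodule, config)


@dataclass
class MatchResult:
    study_id: str
    vendor_id: str
    #: (detection_id, nodule_id, center distance mm) for every TP pair
    pairs: List[Tuple[str, str, float]] = field(default_factory=list)
    detection_labels: Dict[str, str] = field(default_factory=dict)
    nodule_labels: Dict[str, str] = field(default_factory=dict)

    def count(self, label: str) -> int:
        return sum(1 for v in self.detection_labels.values() if v == label)

    @property
    def n_tp(self) -> int:
        return self.count("TP")

    @property
    def n_fn(self) -> int:
        return sum(1 for v in self.nodule_labels.values() if v == "missed")


def match_study(
    detections: Sequence[VendorDetection],
    eligible_nodules: Sequence[ConsensusNodule],
    ignored_nodules: Sequence[ConsensusNodule] = (),
    config: EvalConfig = None,
) -> MatchResult:
    """Label every detection and every eligible nodule of one study."""
    if config is None:
        config = EvalConfig()
    studies = (
        {d.study_id for d in detections}
        | {n.study_id for n in eligible_nodules}
        | {n.study_id for n in ignored_nodules}
    )
    if len(studies) > 1:
        raise ValidationError(f"records span multiple studies: {sorted(studies)}")
    study_id = studies.pop() if studies else ""
    vendor_ids = {d.vendor_id for d in detections}
    if len(vendor_ids) > 1:
        raise ValidationError(f"detections from multiple vendors: {sorted(vendor_ids)}")
    vendor_id = vendor_ids.pop() if vendor_ids else ""

    result = MatchResult(study_id=study_id, vendor_id=vendor_id)
    calcified = [n for n in ignored_nodules if n.eligibility == "ignored_calcified"]
    out_of_range = [n for n in ignored_nodules if n.eligibility == "ignored_size"]

    # Stage 1: detections of masked (calcified) lesions leave the accounting.
    active: List[VendorDetection] = []
    for det in sorted(detections, key=lambda d: d.detection_id):
        if any(is_hit(det, n, config) for n in calcified):
            result.detection_labels[det.detection_id] = "ignored_calcified_hit"
        else:
            active.append(det)

    nodules = sorted(eligible_nodules, key=lambda n: n.nodule_id)

    # Stage 2: maximum-cardinality min-distance assignment on the hit graph.
    matched_nodules: Dict[str, str] = {}  # nodule_id -> detection_id
    if active and nodules:
        cost = np.full((len(active), len(nodules)), _NON_HIT_COST)
        hit = np.zeros_like(cost, dtype=bool)
        for i, det in enumerate(active):
            for j, nod in enumerate(nodules):
                if is_hit(det, nod, config):
                    hit[i, j] = True
                    # epsilon rank keeps exact-distance ties lexicographic
                    cost[i, j] = det.center.distance_to(nod.center) + _LEX_EPSILON * (
                        i * len(nodules) + j
                    )
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if hit[i, j]:
                det, nod = active[i], nodules[j]
                distance = det.center.distance_to(nod.center)
                result.pairs.append((det.detection_id, nod.nodule_id, distance))
                result.detection_labels[det.detection_id] = "TP"
                result.nodule_labels[nod.nodule_id] = "detected"
                matched_nodules[nod.nodule_id] = det.detection_id
    result.pairs.sort()

    # Stage 3: label the leftovers.
    nodules_by_id = {n.nodule_id: n for n in nodules}
    for det in active:
        if det.detection_id in result.detection_labels:
            continue
        hits_matched = any(
            is_hit(det, nodules_by_id[nid], config) for nid in matched_nodules
        )
        if hits_matched:
            result.detection_labels[det.detection_id] = "duplicate"
        elif any(is_hit(det, n, config) for n in out_of_range):
            result.detection_labels[det.detection_id] = "ignored_out_of_range_hit"
        else:
            result.detection_labels[det.detection_id] = "FP"
    for nod in nodules:
        result.nodule_labels.setdefault(nod.nodule_id, "missed")

    assert result.n_tp == sum(
        1 for v in result.nodule_labels.values() if v == "detected"
    )
    return result
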