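"""End-to-end evaluation: reader files -> consensus -> matching -> metrics.

Thin orchestration over the component modules, shared by the CLI, the test
suite and the reproduction script.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .consensus import consensus_for_study
from .matching import MatchResult, match_study
from .metrics import ConfusionCounts, metrics_frame, tabulate
from .model import ConsensusNodule, EvalConfig, ReaderAnnotation, VendorDetection


def build_ground_truth(
    annotations: Sequence[ReaderAnnotation], config: EvalConfig
) -> Tuple[List[ConsensusNodule], List[ConsensusNodule]]:
    """Consensus over all studies; returns (eligible, ignored) nodules."""
    by_study: Dict[str, list] = defaultdict(list)
    for a in annotations:
        by_study[a.study_id].append(a)
    eligible: List[ConsensusNodule] = []
    ignored: List[ConsensusNodule] = []
    for study_id in sorted(by_study):
        e, i = consensus_for_study(by_study[study_id], config)
        eligible.extend(e)
        ignored.extend(i)
    return eligible, ignored


def match_vendor(
    detections: Sequence[VendorDetection],
    eligible: Sequence[ConsensusNodule],
    ignored: Sequence[ConsensusNodule],
    config: EvalConfig,
) -> List[MatchResult]:
    """Per-study matching for one vendor across the whole cohort.

    Studies with ground truth but no detections still yield a result (all
    nodules missed)."""
    det_by_study: Dict[str, list] = defaultdict(list)
    for d in detections:
        det_by_study[d.study_id].append(d)
    eli_by_study: Dict[str, list] = defaultdict(list)
    for n in eligible:
        eli_by_study[n.study_id].append(n)
    ign_by_study: Dict[str, list] = defaultdict(list)
    for n in ignored:
        ign_by_study[n.study_id].append(n)
    vendor_ids = {d.vendor_id for d in detections}
    vendor_id = vendor_ids.pop() if len(vendor_ids) == 1 else ""
    results = []
    for study_id in sorted(set(det_by_study) | set(eli_by_study) | set(ign_by_study)):
        result = match_study(
            det_by_study.get(study_id, []),
            eli_by_study.get(study_id, []),
            ign_by_study.get(study_id, []),
            config,
        )
        if not result.study_id:
            result.study_id = study_id
        if not result.vendor_id:
            result.vendor_id = vendor_id
        results.append(result)
    return results


def evaluate_vendors(
    annotations: Sequence[ReaderAnnotation],
    detections_by_vendor: Dict[str, Sequence[VendorDetection]],
    config: EvalConfig = None,
):
    """Full evaluation of several vendors against one reader cohort.

    Returns (eligible, ignored, match_results, counts, metrics table).
    """
    if config is None:
        config = EvalConfig()
    eligible, ignored = build_ground_truth(annotations, config)
    all_results: List[MatchResult] = []
    all_detections: List[VendorDetection] = []
    for vendor_id in sorted(detections_by_vendor):
        dets = list(detections_by_vendor[vendor_id])
        all_detections.extend(dets)
        all_results.extend(match_vendor(dets, eligible, ignored, config))
    counts = tabulate(all_results, eligible + ignored, all_detections, config)
    table = metrics_frame(counts, config)
    return eligible, ignored, all_results, counts, table


def match_report_frame(results: Sequence[MatchResult]) -> pd.DataFrame:
    """One row per detection and per nodule, with labels and pair distances."""
    rows = []
    for r in results:
        distance_by_det = {d: dist for d, _n, dist in r.pairs}
        nodule_by_det = {d: n for d, n, _dist in r.pairs}
        for det_id, label in sorted(r.detection_labels.items()):
            rows.append(
                {
                    "study_id": r.study_id,
                    "vendor_id": r.vendor_id,
                    "record": "detection",
                    "record_id": det_id,
                    "label": label,
                    "matched_id": nodule_by_det.get(det_id),
                    "distance_mm": distance_by_det.get(det_id),
                }
            )
        det_by_nodule = {n: d for d, n, _dist in r.pairs}
        for nodule_id, label in sorted(r.nodule_labels.items()):
            rows.append(
                {
                    "study_id": r.study_id,
                    "vendor_id": r.vendor_id,
                    "record": "nodule",
                    "record_id": nodule_id,
                    "label": label,
                    "matched_id": det_by_nodule.get(nodule_id),
                    "distance_mm": None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "study_id",
            "vendor_id",
            "record",
            "record_id",
            "label",
            "matched_id",
            "distance_mm",
        ],
    )
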