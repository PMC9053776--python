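"""Confusion tallies and performance metrics for nodule detection.

Counts are tabulated overall and per composition stratum (solid,
ground-glass, part-solid). True positives and false negatives take the
stratum of the matched/missed ground-truth nodule; a false positive has no
ground-truth composition, so it is stratified by the vendor's predicted
composition when one is present and otherwise counted only in the overall
row.

True negatives have no nodule-level meaning in a detection task, so they are
defined at study level: a study contributes one TN to a stratum when it has
no eligible ground-truth nodule of that stratum and the vendor reported no
counted detection of that stratum there. Sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP) on those tallies.

The empirical ROC AUC is the Mann-Whitney statistic (ties count 1/2), with a
seeded stratified percentile bootstrap for the 95% CI (default 2000
replicates) or the Hanley-McNeil parametric interval as an alternative.
When an algorithm emits no scores, only a single operating point is
available and the trapezoid AUC (Se+Sp)/2 is reported, with an optional
bootstrap over studies.

Reported values are round-half-up at ``rounding_decimals`` (default 2); the
raw value is always preserved alongside.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import COMPOSITIONS, ConsensusNodule, EvalConfig, VendorDetection
from .matching import MatchResult

STRATA = ("overall",) + COMPOSITIONS


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is empty — undefined, as opposed to zero."""


def round_metric(x: float, decimals: int = 2) -> float:
    """Round-half-up at ``decimals`` (0.125 -> 0.13 with decimals=2)."""
    if not np.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    stratum: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: Optional[int] = None

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be non-negative")


@dataclass
class MetricValue:
    name: str
    value: float  # raw
    n_effective: int
    rounded: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low - 1e-12 <= self.value <= self.ci_high + 1e-12):
                raise ValueError(
                    f"{self.name}: CI [{self.ci_low}, {self.ci_high}] does not "
                    f"contain the point estimate {self.value}"
                )


def _metric(name: str, num: int, den: int, config: EvalConfig) -> MetricValue:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: empty denominator")
    value = num / den
    return MetricValue(
        name=name,
        value=value,
        n_effective=den,
        rounded=round_metric(value, config.rounding_decimals),
    )


def recall(counts: ConfusionCounts, config: EvalConfig = EvalConfig()) -> MetricValue:
    """TP / (TP + FN)."""
    return _metric("recall", counts.tp, counts.tp + counts.fn, config)


def precision(counts: ConfusionCounts, config: EvalConfig = EvalConfig()) -> MetricValue:
    """TP / (TP + FP)."""
    return _metric("precision", counts.tp, counts.tp + counts.fp, config)


def sensitivity_specificity(
    counts: ConfusionCounts, config: EvalConfig = EvalConfig()
) -> Tuple[MetricValue, MetricValue]:
    """(TP/(TP+FN), TN/(TN+FP)); requires the study-level TN tally."""
    if counts.tn is None:
        raise UndefinedMetricError("specificity undefined: no TN tally")
    sens = _metric("sensitivity", counts.tp, counts.tp + counts.fn, config)
    spec = _metric("specificity", counts.tn, counts.tn + counts.fp, config)
    return sens, spec


def _counted_detection(label: str, config: EvalConfig) -> bool:
    if label == "FP":
        return True
    if label == "duplicate":
        return config.duplicate_policy == "fp"
    if label == "ignored_out_of_range_hit":
        return config.count_out_of_range_hits_as_fp
    return label == "TP"


def tabulate(
    match_results: Sequence[MatchResult],
    nodules: Sequence[ConsensusNodule],
    detections: Sequence[VendorDetection],
    config: EvalConfig = EvalConfig(),
) -> Dict[Tuple[str, str], ConfusionCounts]:
    """Confusion counts per (vendor, stratum), including the overall row.

    ``nodules`` must cover every consensus nodule referenced by the match
    results (for TP/FN stratification); ``detections`` must cover every
    detection (for FP stratification by predicted composition and for the
    study-level TN tally).
    """
    nodules_by_id = {n.nodule_id: n for n in nodules}
    det_by_key = {(d.vendor_id, d.detection_id): d for d in detections}
    vendors = sorted({m.vendor_id for m in match_results})
    studies = sorted({m.study_id for m in match_results})

    out: Dict[Tuple[str, str], ConfusionCounts] = {
        (v, s): ConfusionCounts(stratum=s) for v in vendors for s in STRATA
    }
    # detections that count as FP-or-TP per (vendor, study, stratum), for TN
    counted: Dict[Tuple[str, str], set] = {}

    for m in match_results:
        for nodule_id, label in m.nodule_labels.items():
            nod = nodules_by_id.get(nodule_id)
            if nod is None:
                raise ValueError(f"unknown nodule {nodule_id} in match result")
            strata = ("overall", nod.composition)
            for s in strata:
                if label == "detected":
                    out[(m.vendor_id, s)].tp += 1
                else:
                    out[(m.vendor_id, s)].fn += 1
        for det_id, label in m.detection_labels.items():
            det = det_by_key.get((m.vendor_id, det_id))
            if det is None:
                raise ValueError(f"unknown detection {det_id} in match result")
            fp_counts = label != "TP" and _counted_detection(label, config)
            if fp_counts:
                out[(m.vendor_id, "overall")].fp += 1
                if det.predicted_composition is not None:
                    out[(m.vendor_id, det.predicted_composition)].fp += 1
            if _counted_detection(label, config):
                key = (m.vendor_id, m.study_id)
                counted.setdefault(key, set()).add(
                    det.predicted_composition  # may be None
                )

    # study-level TN tally
    nodule_strata_by_study: Dict[str, set] = {s: set() for s in studies}
    for n in nodules:
        if n.eligibility == "eligible" and n.study_id in nodule_strata_by_study:
            nodule_strata_by_study[n.study_id].add(n.composition)
    for v in vendors:
        for s in STRATA:
            tn = 0
            for study in studies:
                has_counted = counted.get((v, study), set())
                if s == "overall":
                    clean = not nodule_strata_by_study[study] and not has_counted
                else:
                    clean = (
                        s not in nodule_strata_by_study[study]
                        and s not in has_counted
                    )
                tn += int(clean)
            out[(v, s)].tn = tn
    return out


def empirical_auc(outcomes, scores) -> float:
    """Mann-Whitney AUC (ties count 1/2), no interval.

    Computed from tied ranks: AUC = (R1 - n1(n1+1)/2) / (n1 n0) where R1 is
    the rank sum of the positive scores.
    """
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: need both classes")
    ranks = rankdata(s)
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


_auc_value = empirical_auc


def roc_auc(
    outcomes: Sequence[int],
    scores: Sequence[float],
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    config: EvalConfig = EvalConfig(),
) -> MetricValue:
    """Empirical AUC (Mann-Whitney, ties = 1/2) with a 95% CI.

    ``method`` is ``"bootstrap"`` (stratified percentile bootstrap, seeded)
    or ``"hanley_mcneil"`` (parametric).
    """
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("outcomes and scores must be 1-D and congruent")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: need both classes")
    value = _auc_value(y, s)
    if method == "hanley_mcneil":
        q1 = value / (2.0 - value)
        q2 = 2.0 * value**2 / (1.0 + value)
        se = np.sqrt(
            (
                value * (1.0 - value)
                + (n_pos - 1) * (q1 - value**2)
                + (n_neg - 1) * (q2 - value**2)
            )
            / (n_pos * n_neg)
        )
        lo, hi = max(0.0, value - 1.96 * se), min(1.0, value + 1.96 * se)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_scores = s[y == 1]
        neg_scores = s[y == 0]
        replicates = np.empty(n_boot)
        for b in range(n_boot):
            ps = rng.choice(pos_scores, size=n_pos, replace=True)
            ns = rng.choice(neg_scores, size=n_neg, replace=True)
            yy = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
            replicates[b] = _auc_value(yy, np.concatenate([ps, ns]))
        lo, hi = np.percentile(replicates, [2.5, 97.5])
        lo, hi = min(lo, value), max(hi, value)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return MetricValue(
        name="auc",
        value=value,
        n_effective=len(y),
        rounded=round_metric(value, config.rounding_decimals),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def single_point_auc(
    sensitivity: float,
    specificity: float,
    per_study: Optional[Sequence[Tuple[int, int, int, int]]] = None,
    n_boot: int = 2000,
    seed: int = 0,
    config: EvalConfig = EvalConfig(),
) -> MetricValue:
    """Trapezoid AUC from one operating point: (Se + Sp) / 2.

    When per-study confusion tuples (tp, fp, fn, tn) are given, a seeded
    bootstrap over studies yields a 95% CI.
    """
    value = (sensitivity + specificity) / 2.0
    lo = hi = None
    n = 0
    if per_study is not None:
        table = np.asarray(per_study, dtype=float)
        n = len(table)
        rng = np.random.default_rng(seed)
        replicates = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            tp, fp, fn, tn = table[idx].sum(axis=0)
            if tp + fn == 0 or tn + fp == 0:
                continue
            replicates.append((tp / (tp + fn) + tn / (tn + fp)) / 2.0)
        if replicates:
            lo, hi = np.percentile(replicates, [2.5, 97.5])
            lo, hi = float(min(lo, value)), float(max(hi, value))
    return MetricValue(
        name="auc",
        value=value,
        n_effective=n,
        rounded=round_metric(value, config.rounding_decimals),
        ci_low=lo,
        ci_high=hi,
    )


def cohort_summary(nodules: Sequence[ConsensusNodule]) -> Dict[str, pd.DataFrame]:
    """Frequency and size tables describing a ground-truth cohort."""
    if not nodules:
        raise ValueError("empty cohort")
    frame = pd.DataFrame(
        {
            "lobe": [n.lobar_location for n in nodules],
            "composition": [n.composition for n in nodules],
            "spiculated": [n.spiculated for n in nodules],
            "avg_diameter_mm": [n.avg_diameter_mm for n in nodules],
        }
    )
    total = len(frame)

    def _freq(column: str) -> pd.DataFrame:
        counts = frame[column].value_counts()
        return pd.DataFrame(
            {"count": counts, "percent": (100.0 * counts / total).round(2)}
        )

    sizes = []
    for label, sub in [("overall", frame)] + [
        (c, frame[frame.composition == c]) for c in COMPOSITIONS
    ]:
        if len(sub) == 0:
            continue
        d = sub.avg_diameter_mm
        q1, q3 = d.quantile([0.25, 0.75])
        sizes.append(
            {
                "stratum": label,
                "n": len(sub),
                "mean_mm": d.mean(),
                "median_mm": d.median(),
                "q1_mm": q1,
                "q3_mm": q3,
                "iqr_mm": q3 - q1,
            }
        )
    return {
        "location": _freq("lobe"),
        "attenuation": _freq("composition"),
        "spiculation": _freq("spiculated"),
        "size": pd.DataFrame(sizes).set_index("stratum"),
    }


def metrics_frame(
    counts: Dict[Tuple[str, str], ConfusionCounts],
    config: EvalConfig = EvalConfig(),
) -> pd.DataFrame:
    """Flatten per-(vendor, stratum) counts into the standard report table."""
    rows = []
    for (vendor, stratum), c in sorted(counts.items()):
        row = {
            "vendor": vendor,
            "stratum": stratum,
            "tp": c.tp,
            "fp": c.fp,
            "fn": c.fn,
            "tn": c.tn,
        }
        for fn_, key in ((recall, "recall"), (precision, "precision")):
            try:
                m = fn_(c, config)
                row[f"{key}_raw"] = m.value
                row[key] = m.rounded
            except UndefinedMetricError:
                row[f"{key}_raw"] = None
                row[key] = None
        try:
            sens, spec = sensitivity_specificity(c, config)
            row["sensitivity"] = sens.rounded
            row["specificity"] = spec.rounded
        except UndefinedMetricError:
            row["sensitivity"] = None
            row["specificity"] = None
        rows.append(row)
    frame = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(STRATA)}
    return (
        frame.assign(_o=frame.stratum.map(order))
        .sort_values(["vendor", "_o"])
        .drop(columns="_o")
        .reset_index(drop=True)
    )
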