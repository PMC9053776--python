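"""Confusion tallies, detection metrics, rounding, and AUC machinery."""
import itertools

import numpy as np
import pytest

from noduleval.matching import match_study
from noduleval.metrics import (
    ConfusionCounts,
    UndefinedMetricError,
    cohort_summary,
    empirical_auc,
    metrics_frame,
    precision,
    recall,
    roc_auc,
    round_metric,
    sensitivity_specificity,
    single_point_auc,
    tabulate,
)
from noduleval.model import EvalConfig
from _factories import detection, nodule

CONFIG = EvalConfig()


@pytest.mark.parametrize(
    "value,expected",
    [(0.7984, 0.80), (0.4027, 0.40), (0.2517, 0.25), (0.125, 0.13), (0.5, 0.5)],
)
def test_round_half_up(value, expected):
    assert round_metric(value, 2) == expected


@pytest.mark.parametrize(
    "tp,fn,expected",
    [(194, 49, 0.80), (36, 4, 0.90), (0, 5, 0.00)],
)
def test_recall_from_counts(tp, fn, expected):
    m = recall(ConfusionCounts("overall", tp=tp, fn=fn))
    assert m.rounded == expected
    assert m.value == pytest.approx(tp / (tp + fn))


@pytest.mark.parametrize(
    "tp,fp,expected",
    [(194, 23, 0.89), (182, 270, 0.40), (36, 107, 0.25)],
)
def test_precision_from_counts(tp, fp, expected):
    assert precision(ConfusionCounts("overall", tp=tp, fp=fp)).rounded == expected


def test_undefined_metrics_raise_not_zero():
    with pytest.raises(UndefinedMetricError):
        recall(ConfusionCounts("overall"))
    with pytest.raises(UndefinedMetricError):
        precision(ConfusionCounts("overall"))
    with pytest.raises(UndefinedMetricError):
        sensitivity_specificity(ConfusionCounts("overall", tp=1, fn=1))  # no TN


def test_sensitivity_specificity_pairs():
    sens, spec = sensitivity_specificity(
        ConfusionCounts("overall", tp=10, fn=0, fp=0, tn=5)
    )
    assert (sens.value, spec.value) == (1.0, 1.0)
    sens, spec = sensitivity_specificity(
        ConfusionCounts("overall", tp=105, fn=22, fp=16, tn=29)
    )
    assert sens.value == pytest.approx(0.8268, abs=1e-4)
    assert spec.value == pytest.approx(29 / 45)
    _, spec = sensitivity_specificity(ConfusionCounts("overall", tp=1, fn=0, fp=5, tn=0))
    assert spec.value == 0.0


def _one_study_setup():
    """Two solid + one ground-glass nodule; vendor finds both solid ones,
    adds one ground-glass-labelled FP and one unlabelled FP."""
    nodules = [
        nodule(nid="N1", x=0, composition="solid"),
        nodule(nid="N2", x=60, composition="solid"),
        nodule(nid="N3", x=120, composition="ground_glass"),
    ]
    detections = [
        detection(did="D1", x=1, composition="solid"),
        detection(did="D2", x=61, composition="solid"),
        detection(did="D3", x=200, composition="ground_glass"),
        detection(did="D4", x=240),
    ]
    result = match_study(detections, nodules, [], CONFIG)
    return nodules, detections, [result]


def test_tabulate_stratifies_and_conserves():
    nodules, detections, results = _one_study_setup()
    counts = tabulate(results, nodules, detections, CONFIG)
    overall = counts[("V1", "overall")]
    solid = counts[("V1", "solid")]
    gg = counts[("V1", "ground_glass")]
    ps = counts[("V1", "part_solid")]
    assert (overall.tp, overall.fp, overall.fn) == (2, 2, 1)
    assert (solid.tp, solid.fn) == (2, 0)
    assert (gg.tp, gg.fn) == (0, 1)
    # FP with a predicted composition lands in that stratum; the unlabelled
    # one counts only in the overall row
    assert gg.fp == 1 and solid.fp == 0 and ps.fp == 0
    assert solid.tp + gg.tp + ps.tp == overall.tp
    assert solid.fn + gg.fn + ps.fn == overall.fn


def test_study_level_tn_counts_clean_studies():
    nodules = [nodule(nid="N1", study="S1", composition="solid")]
    detections = [detection(did="D1", study="S1", composition="solid")]
    r1 = match_study(detections, nodules, [], CONFIG)
    r2 = match_study([], [], [], CONFIG)
    r2.study_id, r2.vendor_id = "S2", "V1"
    counts = tabulate([r1, r2], nodules, detections, CONFIG)
    # S2 has neither nodules nor detections: one TN everywhere; S1 is clean
    # only for the strata it does not touch
    assert counts[("V1", "overall")].tn == 1
    assert counts[("V1", "solid")].tn == 1
    assert counts[("V1", "ground_glass")].tn == 2
    assert counts[("V1", "part_solid")].tn == 2


def test_perfect_cohort_has_no_errors():
    nodules = [nodule(nid=f"N{i}", x=40.0 * i) for i in range(4)]
    detections = [detection(did=f"D{i}", x=40.0 * i) for i in range(4)]
    result = match_study(detections, nodules, [], CONFIG)
    counts = tabulate([result], nodules, detections, CONFIG)
    overall = counts[("V1", "overall")]
    assert (overall.tp, overall.fp, overall.fn) == (4, 0, 0)
    assert recall(overall).value == 1.0 and precision(overall).value == 1.0


def brute_force_auc(outcomes, scores) -> float:
    pos = [s for y, s in zip(outcomes, scores) if y == 1]
    neg = [s for y, s in zip(outcomes, scores) if y == 0]
    total = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return total / (len(pos) * len(neg))


@pytest.mark.parametrize(
    "outcomes,scores,expected",
    [
        ([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.1], 1.0),
        ([1, 1, 0, 0], [0.9, 0.4, 0.7, 0.1], 0.75),
        ([1, 0], [0.5, 0.5], 0.5),
    ],
)
def test_empirical_auc_examples(outcomes, scores, expected):
    assert empirical_auc(outcomes, scores) == pytest.approx(expected)
    assert brute_force_auc(outcomes, scores) == pytest.approx(expected)


def test_empirical_auc_agrees_with_sklearn_on_random_instances():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(3, 40))
        outcomes = rng.integers(0, 2, n)
        if outcomes.sum() in (0, n):
            continue
        scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
        assert empirical_auc(outcomes, scores) == pytest.approx(
            float(sklearn_metrics.roc_auc_score(outcomes, scores))
        )


def test_auc_requires_both_classes():
    with pytest.raises(UndefinedMetricError):
        roc_auc([1, 1], [0.5, 0.6])


def test_bootstrap_and_hanley_mcneil_cis_contain_estimate():
    rng = np.random.default_rng(0)
    outcomes = np.array([1] * 30 + [0] * 30)
    scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
    for method in ("bootstrap", "hanley_mcneil"):
        m = roc_auc(outcomes, scores, method=method, n_boot=300, seed=4)
        assert m.ci_low <= m.value <= m.ci_high
        assert 0.0 <= m.ci_low and m.ci_high <= 1.0


def test_bootstrap_ci_narrows_with_more_data():
    rng = np.random.default_rng(1)

    def width(n):
        outcomes = np.array([1] * n + [0] * n)
        scores = np.concatenate([rng.normal(0.8, 1, n), rng.normal(0, 1, n)])
        m = roc_auc(outcomes, scores, n_boot=400, seed=2)
        return m.ci_high - m.ci_low

    assert width(200) < width(15)


def test_single_point_auc_closed_form():
    m = single_point_auc(0.83, 0.644)
    assert m.value == pytest.approx(0.737)
    assert m.rounded == 0.74


def test_single_point_auc_bootstrap_over_studies():
    per_study = [(2, 1, 1, 3), (1, 0, 1, 4), (3, 2, 0, 2)] * 5
    m = single_point_auc(0.75, 0.7, per_study=per_study, n_boot=300, seed=0)
    assert m.ci_low <= m.value <= m.ci_high


def test_cohort_summary_frequencies_and_sizes():
    nodules = (
        [nodule(nid=f"s{i}", composition="solid", avg=4.0 + i) for i in range(5)]
        + [nodule(nid="g1", composition="ground_glass", avg=6.0)]
    )
    tables = cohort_summary(nodules)
    att = tables["attenuation"]
    assert att.loc["solid", "count"] == 5
    assert att.loc["solid", "percent"] == pytest.approx(83.33)
    assert tables["location"].loc["RUL", "percent"] == 100.0
    sizes = tables["size"]
    assert sizes.loc["solid", "median_mm"] == 6.0
    assert sizes.loc["solid", "mean_mm"] == 6.0


def test_metrics_frame_layout():
    nodules, detections, results = _one_study_setup()
    counts = tabulate(results, nodules, detections, CONFIG)
    frame = metrics_frame(counts, CONFIG)
    assert list(frame.stratum[:4]) == ["overall", "solid", "ground_glass", "part_solid"]
    overall = frame[frame.stratum == "overall"].iloc[0]
    assert overall.recall == round_metric(2 / 3)
    assert overall.precision == 0.5
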