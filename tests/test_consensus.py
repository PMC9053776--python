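"""Inter-reader clustering and majority-consensus ground truth."""
import dataclasses

import numpy as np
import pytest

from noduleval.consensus import (
    build_consensus,
    cluster_annotations,
    consensus_for_study,
)
from noduleval.model import EvalConfig, Point3D, ValidationError
from _factories import annotation

CONFIG = EvalConfig()


def _triple(x=0.0, y=0.0, z=0.0, **kwargs):
    return [
        annotation(x=x, y=y, z=z, reader=r, aid=f"{r}-a", **kwargs)
        for r in ("R1", "R2", "R3")
    ]


def test_identical_annotations_form_one_cluster():
    clusters = cluster_annotations(_triple(), CONFIG)
    assert len(clusters) == 1
    assert len(clusters[0].members) == 3


def test_distant_annotations_stay_apart():
    annotations = [
        annotation(x=0, reader="R1", aid="a"),
        annotation(x=50, reader="R2", aid="b"),
    ]
    clusters = cluster_annotations(annotations, CONFIG)
    assert [len(c.members) for c in clusters] == [1, 1]


def test_chain_links_transitively():
    # A-B and B-C within the criterion, A-C not: one 3-member component
    a = annotation(x=0, reader="R1", aid="A", long_axis=12, short_axis=12)
    b = annotation(x=9, reader="R2", aid="B", long_axis=12, short_axis=12)
    c = annotation(x=18, reader="R3", aid="C", long_axis=12, short_axis=12)
    clusters = cluster_annotations([a, b, c], CONFIG)
    assert len(clusters) == 1
    assert {m.annotation_id for m in clusters[0].members} == {"A", "B", "C"}


def test_clustering_matches_networkx_components():
    networkx = pytest.importorskip("networkx")
    from noduleval.model import annotations_correspond

    rng = np.random.default_rng(42)
    for _ in range(30):
        annotations = []
        for i in range(int(rng.integers(2, 9))):
            reader = f"R{int(rng.integers(1, 4))}"
            annotations.append(
                annotation(
                    x=float(rng.uniform(0, 60)),
                    y=float(rng.uniform(0, 60)),
                    z=float(rng.uniform(0, 60)),
                    reader=reader,
                    aid=f"a{i}",
                    long_axis=float(rng.uniform(6, 14)),
                    short_axis=6.0,
                )
            )
        graph = networkx.Graph()
        graph.add_nodes_from(a.annotation_id for a in annotations)
        for i, a in enumerate(annotations):
            for b in annotations[i + 1 :]:
                if a.reader_id != b.reader_id and annotations_correspond(a, b, CONFIG):
                    graph.add_edge(a.annotation_id, b.annotation_id)
        expected = {
            frozenset(component)
            for component in networkx.connected_components(graph)
        }
        got = {
            frozenset(m.annotation_id for m in c.members)
            for c in cluster_annotations(annotations, CONFIG)
        }
        assert got == expected


def test_mixed_studies_rejected():
    with pytest.raises(ValidationError):
        cluster_annotations(
            [annotation(study="S1", reader="R1"), annotation(study="S2", reader="R2")],
            CONFIG,
        )


def test_single_reader_cluster_is_dropped():
    eligible, ignored = consensus_for_study(
        [annotation(reader="R1", aid="solo")], CONFIG
    )
    assert eligible == [] and ignored == []


def test_two_reader_cluster_is_kept_with_aggregates():
    annotations = [
        annotation(x=0, reader="R1", aid="a", long_axis=10, short_axis=6),
        annotation(x=2, reader="R2", aid="b", long_axis=12, short_axis=8),
    ]
    eligible, ignored = consensus_for_study(annotations, CONFIG)
    assert len(eligible) == 1 and not ignored
    nodule = eligible[0]
    assert nodule.center == Point3D(1.0, 0.0, 0.0)
    assert nodule.avg_diameter_mm == pytest.approx(9.0)  # mean of 8 and 10
    assert nodule.supporting_reader_ids == frozenset({"R1", "R2"})


def test_small_consensus_nodule_is_size_ignored():
    annotations = [
        annotation(reader=r, aid=r, long_axis=4.0, short_axis=3.0) for r in ("R1", "R2")
    ]
    _, ignored = consensus_for_study(annotations, CONFIG)
    assert ignored[0].eligibility == "ignored_size"
    assert ignored[0].avg_diameter_mm == pytest.approx(3.5)


def test_any_calcified_flag_masks_the_nodule():
    annotations = [
        annotation(reader="R1", aid="a", calcified=True),
        annotation(reader="R2", aid="b", calcified=False),
    ]
    _, ignored = consensus_for_study(annotations, CONFIG)
    assert ignored[0].eligibility == "ignored_calcified"


def test_composition_majority_and_tie_precedence():
    majority = _triple()
    majority[2] = dataclasses.replace(majority[2], composition="ground_glass")
    eligible, _ = consensus_for_study(majority, CONFIG)
    assert eligible[0].composition == "solid"
    assert not eligible[0].composition_tie

    tied = [
        annotation(reader="R1", aid="a", composition="solid"),
        annotation(
            reader="R2",
            aid="b",
            composition="part_solid",
            solid_long=4.0,
            solid_short=3.0,
        ),
    ]
    eligible, _ = consensus_for_study(tied, CONFIG)
    assert eligible[0].composition == "part_solid"
    assert eligible[0].composition_tie


def test_three_identical_reader_files_reproduce_ground_truth():
    base = [
        dict(x=10.0, y=20.0, z=30.0, long_axis=10.0, short_axis=6.0, composition="solid"),
        dict(
            x=80.0,
            y=90.0,
            z=40.0,
            long_axis=14.0,
            short_axis=10.0,
            composition="part_solid",
            solid_long=6.0,
            solid_short=4.0,
            lobe="LLL",
            laterality="left",
            spiculated=True,
        ),
    ]
    annotations = [
        annotation(reader=r, aid=f"{r}-{i}", **spec)
        for r in ("R1", "R2", "R3")
        for i, spec in enumerate(base)
    ]
    eligible, ignored = consensus_for_study(annotations, CONFIG)
    assert not ignored
    assert len(eligible) == len(base)
    for nodule, spec in zip(
        sorted(eligible, key=lambda n: n.center.x_mm),
        sorted(base, key=lambda s: s["x"]),
    ):
        assert nodule.center == Point3D(spec["x"], spec["y"], spec["z"])
        assert nodule.avg_diameter_mm == pytest.approx(
            (spec["long_axis"] + spec["short_axis"]) / 2
        )
        assert nodule.composition == spec["composition"]
        assert nodule.spiculated == spec.get("spiculated", False)
        assert len(nodule.supporting_reader_ids) == 3


def test_cluster_count_bounds():
    annotations = _triple() + [annotation(x=60, reader="R1", aid="far")]
    clusters = cluster_annotations(annotations, CONFIG)
    eligible, ignored = build_consensus(clusters, CONFIG)
    assert len(eligible) + len(ignored) <= len(clusters) <= len(annotations)


def test_small_perturbations_never_change_the_clustering():
    """Jitter below a third of the hit distance keeps components intact when
    lesions are well separated (>= 25 mm) and not tiny (>= 8 mm)."""
    rng = np.random.default_rng(7)
    centers = [(40.0, 40.0, 40.0), (80.0, 40.0, 40.0), (40.0, 80.0, 90.0)]
    annotations = []
    for k, (x, y, z) in enumerate(centers):
        for reader in ("R1", "R2", "R3"):
            annotations.append(
                annotation(
                    x=x, y=y, z=z, reader=reader, aid=f"n{k}-{reader}",
                    long_axis=10.0, short_axis=8.0,
                )
            )
    baseline = {
        frozenset(m.annotation_id for m in c.members)
        for c in cluster_annotations(annotations, CONFIG)
    }
    for _ in range(25):
        perturbed = []
        for a in annotations:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = direction * rng.uniform(0, CONFIG.hit_distance_mm / 3 * 0.999)
            perturbed.append(
                dataclasses.replace(
                    a,
                    center=Point3D(
                        a.center.x_mm + offset[0],
                        a.center.y_mm + offset[1],
                        a.center.z_mm + offset[2],
                    ),
                )
            )
        got = {
            frozenset(m.annotation_id for m in c.members)
            for c in cluster_annotations(perturbed, CONFIG)
        }
        assert got == baseline
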