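"""Neighbour-joining trees, additivity, topology recovery and early
(trunk) event inference."""

import numpy as np
import pytest

from quadclone.events import AberrationEvent, Endpoint, EventKind, EventMatrix
from quadclone.genome import GenomeModel
from quadclone.phylogeny import build_tree, infer_early_events, order_chromosome_events
from quadclone.synthetic import SimulationConfig, leaf_clones, simulate_clone_phylogeny


def matrix_from_sets(case, sample_events):
    """EventMatrix from {sample: set-of-event-indices}; events are
    synthetic 5-Mb gains indexed along chromosome 1."""
    n = max((max(s) + 1 for s in sample_events.values() if s), default=1)
    events = [
        AberrationEvent(
            "1", Endpoint.numeric(float(6 * i + 1)),
            Endpoint.numeric(float(6 * i + 5)), EventKind.GAIN,
        )
        for i in range(n)
    ]
    samples = list(sample_events)
    presence = np.zeros((len(samples), n), dtype=bool)
    for r, s in enumerate(samples):
        for i in sample_events[s]:
            presence[r, i] = True
    return EventMatrix(case_id=case, events=events, samples=samples, presence=presence)


def clones_to_matrix(clones, genome):
    """Perfect-detection sample matrix: one sample per leaf clone."""
    leaves = leaf_clones(clones)
    catalogue = sorted(
        {e for leaf in leaves for e in leaf.events},
        key=lambda e: (genome.chrom_index(e.chrom), e.start.mb),
    )
    presence = np.array(
        [[e in leaf.events for e in catalogue] for leaf in leaves], dtype=bool
    )
    samples = [(i + 1, 0) for i in range(len(leaves))]
    return EventMatrix(
        case_id="SIM", events=catalogue, samples=samples, presence=presence
    ), leaves


def test_three_leaf_tree_has_closed_form_branch_lengths():
    """Two samples sharing t=3 trunk events with a=2 / b=4 private events:
    NORMAL-junction = t, junction-leaves = a and b."""
    t, a, b = 3, 2, 4
    m = matrix_from_sets(
        "C",
        {
            (1, 0): set(range(t)) | set(range(t, t + a)),
            (2, 0): set(range(t)) | set(range(t + a, t + a + b)),
        },
    )
    tree = build_tree(m)
    rooted = tree.rooted_at_normal()
    tip_a = rooted.find("C_q1_wk0")
    tip_b = rooted.find("C_q2_wk0")
    assert tip_a.length == pytest.approx(a)
    assert tip_b.length == pytest.approx(b)
    assert tree.tip_distance("NORMAL", "C_q1_wk0") == pytest.approx(t + a)
    assert tree.tip_distance("NORMAL", "C_q2_wk0") == pytest.approx(t + b)
    assert tree.tip_distance("C_q1_wk0", "C_q2_wk0") == pytest.approx(a + b)


def test_identical_samples_form_zero_length_cherry():
    m = matrix_from_sets("C", {(1, 0): {0, 1}, (2, 0): {0, 1}})
    tree = build_tree(m)
    assert tree.tip_distance("C_q1_wk0", "C_q2_wk0") == pytest.approx(0.0)
    assert tree.tip_distance("NORMAL", "C_q1_wk0") == pytest.approx(2.0)


def test_nj_branch_lengths_never_negative(fixture_results):
    for result in fixture_results.values():
        for node in result.tree.tree.traverse():
            if node.length is not None:
                assert node.length >= -1e-12


def test_path_lengths_reproduce_distances_on_perfect_phylogenies(genome):
    """On additive inputs (perfect phylogeny, complete detection) NJ
    reproduces every leaf-to-leaf distance exactly."""
    for seed in range(10):
        config = SimulationConfig(
            n_trunk_events=3, n_lineages=int(2 + seed % 3),
            n_branch_events=2 + seed % 4, seed=seed,
        )
        clones = simulate_clone_phylogeny(config, genome)
        m, _ = clones_to_matrix(clones, genome)
        tree = build_tree(m)
        from quadclone.events import distance_matrix

        ids, dm = distance_matrix(m, include_normal=True)
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                assert tree.tip_distance(a, ids[j]) == pytest.approx(
                    dm[i, j], abs=1e-9
                )


def test_lineage_samples_form_clades_when_rooted_at_normal(genome):
    """Multiple samples per lineage cluster into that lineage's clade."""
    for seed in (1, 2, 3, 4, 5):
        config = SimulationConfig(seed=seed)
        clones = simulate_clone_phylogeny(config, genome)
        leaves = leaf_clones(clones)
        catalogue = sorted(
            {e for leaf in leaves for e in leaf.events}, key=str
        )
        samples, rows = [], []
        for i, leaf in enumerate(leaves):
            for rep in range(2):  # two identical biopsies per lineage
                samples.append((2 * i + rep + 1, 0))
                rows.append([e in leaf.events for e in catalogue])
        m = EventMatrix(
            case_id="SIM", events=catalogue, samples=samples,
            presence=np.array(rows, dtype=bool),
        )
        tree = build_tree(m)
        for i in range(len(leaves)):
            tips = [f"SIM_q{2 * i + 1}_wk0", f"SIM_q{2 * i + 2}_wk0"]
            assert tree.clade_tips(tips), f"seed {seed} lineage {i}"


def test_case13_tree_clades_with_span_weighting(fixture_matrices):
    """With span-weighted distances the tree separates the quadrant-1/2
    lineage from the quadrant-3/4 genotype that also persists at week 5
    in quadrant 2."""
    tree = build_tree(fixture_matrices["CE01-13"], weight="span")
    assert tree.clade_tips(["CE01-13_q1_wk0", "CE01-13_q2_wk0"])
    assert tree.clade_tips(
        ["CE01-13_q3_wk0", "CE01-13_q4_wk0", "CE01-13_q2_wk5"]
    )


def test_fewer_than_two_leaves_rejected():
    m = matrix_from_sets("C", {})
    with pytest.raises(ValueError):
        build_tree(m)


# ---------------------------------------------------------------------------
# early events
# ---------------------------------------------------------------------------

def test_fixture_trunk_events_match_published_early_events(fixture_results):
    expected = {
        "CE01-02": ["3 153.8-q tel Gain"],
        "CE01-13": [
            "15 89.3-q tel Loss",
            "3 141.6-q tel Gain",
            "4 167.4-170.1 Loss",
            "9 p tel-13.2 Loss",
        ],
        "CE01-09": [
            "11 104.4-q tel Loss",
            "11 75.1-98.9 Gain",
            "11 98.9-104.4 Further gain",
        ],
    }
    for case, result in fixture_results.items():
        assert sorted(str(e) for e in result.early.trunk_events) == expected[case]


def test_single_subpopulation_makes_every_event_trunk():
    m = matrix_from_sets("C", {(1, 0): {0, 1, 2}, (2, 0): {0, 1, 2}})
    labels = {(1, 0): "A", (2, 0): "A"}
    report = infer_early_events(m, labels)
    assert len(report.trunk_events) == 3
    assert not report.branch_events


def test_trunk_recovered_exactly_on_perfect_detection(genome):
    for seed in range(5):
        config = SimulationConfig(seed=seed)
        clones = simulate_clone_phylogeny(config, genome)
        m, leaves = clones_to_matrix(clones, genome)
        labels = {s: leaf.clone_id for s, leaf in zip(m.samples, leaves)}
        report = infer_early_events(m, labels)
        assert set(report.trunk_events) == set(clones[0].events)


def test_empty_trunk_flagged():
    m = matrix_from_sets("C", {(1, 0): {0}, (2, 0): {1}})
    labels = {(1, 0): "A", (2, 0): "B"}
    report = infer_early_events(m, labels)
    assert report.empty_trunk_warning
    assert report.trunk_events == []


def test_chromosome11_order_narrative_for_case02(fixture_matrices):
    """Grouping the case-02 samples into pre- vs post-treatment
    populations, the 94.8-q tel loss on 11q predates divergence while the
    other 11q rearrangements are lineage-private."""
    m = fixture_matrices["CE01-02"]
    labels = {s: ("W0" if s[1] == 0 else "W2") for s in m.samples}
    report = infer_early_events(m, labels)
    rows = order_chromosome_events(report, m, labels, "11")
    by_event = {r["event"].position_label: r["order"] for r in rows}
    assert by_event["94.8-q tel"] == "TRUNK"
    assert by_event["74.7-85.3"] == "BRANCH"
    assert by_event["85.3-q tel"] == "BRANCH"
    rows_empty = order_chromosome_events(report, m, labels, "21")
    assert rows_empty == []
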