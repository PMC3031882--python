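"""Event dialect, segment->event conversion, cross-sample matching and
the event distance."""

import itertools

import numpy as np
import pytest

from quadclone.calling import call_segments
from quadclone.events import (
    AberrationEvent,
    Endpoint,
    EventKind,
    EventMatrix,
    distance_matrix,
    event_from_bp,
    match_events,
    pairwise_difference,
    parse_position,
    segments_to_events,
)
from quadclone.pipeline import PipelineConfig, analyze_profiles
from quadclone.preprocessing import Segment
from quadclone.synthetic import SimulationConfig, leaf_clones, simulate_case


def seg(chrom, start_mb, end_mb, mean, n_probes=30):
    return Segment(
        chrom=str(chrom),
        start_bp=int(start_mb * 1e6),
        end_bp=int(end_mb * 1e6),
        n_probes=n_probes,
        mean_log2=mean,
    )


def ev(chrom, position, kind, genome):
    return parse_position(chrom, position, kind, genome)


# ---------------------------------------------------------------------------
# segments_to_events
# ---------------------------------------------------------------------------

def test_terminal_gain_is_qtel_anchored(genome):
    called = call_segments(
        [seg("3", 0.3, 141.6, 0.0), seg("3", 141.6, 199.4, 0.6)]
    )
    events = segments_to_events(called, genome)
    assert len(events) == 1
    assert events[0].kind == EventKind.GAIN
    assert events[0].start.label == "141.6"
    assert events[0].end.label == "q tel"


def test_neutral_only_profile_yields_no_events(genome):
    called = call_segments([seg("1", 0.3, 247.0, 0.02)])
    assert segments_to_events(called, genome) == []


def test_stepped_gain_reported_as_gain_plus_further_gain(genome):
    called = call_segments(
        [
            seg("11", 0.4, 75.1, 0.0),
            seg("11", 75.1, 98.9, 0.55),
            seg("11", 98.9, 104.4, 1.1),
            seg("11", 104.4, 134.0, -0.6),
        ]
    )
    events = segments_to_events(called, genome)
    kinds = [(e.kind, e.start.label, e.end.label) for e in events]
    assert kinds == [
        (EventKind.GAIN, "75.1", "98.9"),
        (EventKind.FURTHER_GAIN, "98.9", "104.4"),
        (EventKind.LOSS, "104.4", "q tel"),
    ]


def test_small_gain_filtered_but_focal_amplicon_kept(genome):
    called = call_segments(
        [
            seg("17", 10.0, 11.0, 0.5, n_probes=3),    # 1 Mb gain: noise
            seg("17", 28.5, 29.7, 2.1, n_probes=3),    # focal amplicon: real
        ]
    )
    events = segments_to_events(called, genome)
    assert [e.kind for e in events] == [EventKind.AMP]


def test_segment_outside_chromosome_rejected(genome):
    called = call_segments([seg("21", 10.0, 60.0, 0.5)])  # chr21 < 47 Mb
    with pytest.raises(ValueError, match="outside"):
        segments_to_events(called, genome)


def test_whole_chromosome_dialect(genome):
    e = ev("18", "Whole chr", EventKind.LOSS, genome)
    assert e.is_whole_chromosome
    assert e.position_label == "Whole chr"
    assert e.start.mb == 0.0
    assert e.end.mb == pytest.approx(76.1, abs=0.1)
    q = ev("1", "q arm", EventKind.GAIN, genome)
    assert q.start.label == "cen" and q.end.label == "q tel"


def test_parse_position_rejects_garbage(genome):
    with pytest.raises(ValueError):
        parse_position("1", "nonsense", EventKind.GAIN, genome)
    with pytest.raises(ValueError):
        parse_position("1", "50.0-20.0", EventKind.GAIN, genome)  # start >= end


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_identical_event_lists_match_into_single_columns(genome):
    events = [
        ev("3", "153.8-q tel", EventKind.GAIN, genome),
        ev("11", "94.8-q tel", EventKind.LOSS, genome),
    ]
    m = match_events({(1, 0): list(events), (2, 0): list(events)}, "C", genome)
    assert len(m.events) == 2
    assert m.presence.all()
    assert pairwise_difference(m, (1, 0), (2, 0)) == 0


def test_nearby_losses_with_tight_tolerance_stay_distinct(genome):
    a = ev("11", "85.3-q tel", EventKind.LOSS, genome)
    b = ev("11", "94.8-q tel", EventKind.LOSS, genome)
    m = match_events({(1, 0): [a], (2, 0): [b]}, "C", genome, tol_mb=1.0)
    assert len(m.events) == 2
    assert pairwise_difference(m, (1, 0), (2, 0)) == 2


def test_jittered_endpoints_within_tolerance_merge(genome):
    a = AberrationEvent("5", Endpoint.numeric(10.0), Endpoint.numeric(40.0), EventKind.GAIN)
    b = AberrationEvent("5", Endpoint.numeric(10.8), Endpoint.numeric(39.5), EventKind.GAIN)
    m = match_events({(1, 0): [a], (2, 0): [b]}, "C", genome, tol_mb=1.0)
    assert len(m.events) == 1


def test_level_aware_matching_keeps_further_gain_separate(genome):
    a = AberrationEvent("19", Endpoint.numeric(30.0), Endpoint.numeric(50.0), EventKind.GAIN)
    b = AberrationEvent("19", Endpoint.numeric(30.0), Endpoint.numeric(50.0), EventKind.FURTHER_GAIN)
    m = match_events({(1, 0): [a], (2, 0): [b]}, "C", genome)
    assert len(m.events) == 2


def test_token_endpoints_match_token_for_token(genome):
    a = ev("19", "Whole chr", EventKind.LOSS, genome)
    b = ev("19", "p tel-cen", EventKind.LOSS, genome)
    m = match_events({(1, 0): [a], (2, 0): [b]}, "C", genome, tol_mb=50.0)
    assert len(m.events) == 2  # q tel endpoint vs cen never merge


def test_case13_quadrants_1_and_3_share_only_hom_rows(fixture_matrices):
    m = fixture_matrices["CE01-13"]
    shared = [
        e
        for e, a, b in zip(m.events, m.row((1, 0)), m.row((3, 0)))
        if a and b
    ]
    assert sorted(str(e) for e in shared) == [
        "15 89.3-q tel Loss",
        "3 141.6-q tel Gain",
        "4 167.4-170.1 Loss",
        "9 p tel-13.2 Loss",
    ]


def test_pairwise_difference_is_a_metric(fixture_matrices):
    for m in fixture_matrices.values():
        for a, b, c in itertools.permutations(m.samples, 3):
            dab = pairwise_difference(m, a, b)
            dbc = pairwise_difference(m, b, c)
            dac = pairwise_difference(m, a, c)
            assert dab == pairwise_difference(m, b, a)  # symmetric
            assert dac <= dab + dbc  # triangle inequality
        for s in m.samples:
            assert pairwise_difference(m, s, s) == 0


def test_span_weighting_emphasises_large_events(genome):
    whole = ev("18", "Whole chr", EventKind.LOSS, genome)
    focal = AberrationEvent("20", Endpoint.numeric(20.5), Endpoint.numeric(22.1), EventKind.LOSS)
    m = match_events({(1, 0): [whole], (2, 0): [focal]}, "C", genome)
    d_count = pairwise_difference(m, (1, 0), (2, 0), weight="count")
    d_span = pairwise_difference(m, (1, 0), (2, 0), weight="span")
    assert d_count == 2
    assert d_span == pytest.approx(whole.span_mb + focal.span_mb)


def test_catalogue_never_exceeds_total_input_events(genome):
    rng = np.random.default_rng(4)
    lists = {}
    total = 0
    for s in range(3):
        evs = []
        for _ in range(5):
            start = rng.uniform(1, 80)
            end = start + rng.uniform(5, 40)
            evs.append(
                AberrationEvent(
                    "2", Endpoint.numeric(round(start, 1)),
                    Endpoint.numeric(round(end, 1)), EventKind.GAIN,
                )
            )
        lists[(s + 1, 0)] = evs
        total += len(evs)
    m = match_events(lists, "C", genome, tol_mb=2.0)
    assert len(m.events) <= total
    ids, dm = distance_matrix(m, include_normal=True)
    assert ids[-1] == "NORMAL"
    assert np.allclose(dm, dm.T)


def test_noiseless_round_trip_recovers_catalogue_token_for_token(genome):
    """Events rendered at full purity with no noise come back through
    segmentation, calling and extraction exactly."""
    case = simulate_case(
        SimulationConfig(seed=17), genome, noise_sd=0.0, cellularity=1.0
    )
    result = analyze_profiles(case.profiles, genome, PipelineConfig(n_perm=200))
    truth = set()
    for leaf in leaf_clones(case.clones):
        truth |= set(leaf.events)
    assert set(result.matrix.events) == truth
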