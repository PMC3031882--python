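"""Tests of the clone-mixture simulator: perfect phylogeny, selection
dynamics, the mixing equation and fixture round trips."""

import numpy as np
import pytest

from quadclone.genome import GenomeModel
from quadclone.synthetic import (
    CellTruth,
    SimulationConfig,
    evolve_fractions,
    fixture_digest,
    leaf_clones,
    read_fixture,
    render_probe_data,
    simulate_case,
    simulate_clone_phylogeny,
    write_fixture,
)


def test_no_events_means_flat_diploid_genome(genome):
    config = SimulationConfig(n_trunk_events=0, n_lineages=1, n_branch_events=0)
    clones = simulate_clone_phylogeny(config, genome)
    leaf = leaf_clones(clones)[0]
    assert leaf.events == frozenset()
    cn = leaf.copy_number(genome)
    assert all(np.all(v == 2) for v in cn.values())


def test_leaves_share_exactly_the_trunk_events(genome):
    config = SimulationConfig(
        n_trunk_events=3, n_lineages=2, n_branch_events=4, seed=7
    )
    clones = simulate_clone_phylogeny(config, genome)
    root = clones[0]
    a, b = leaf_clones(clones)
    assert len(root.events) == 3
    assert a.events & b.events == root.events
    assert len(a.events - root.events) == 4
    assert len(b.events - root.events) == 4
    # perfect phylogeny: children contain all parent events
    assert root.events <= a.events and root.events <= b.events


def test_branch_events_do_not_overlap_across_lineages(genome):
    config = SimulationConfig(
        n_trunk_events=2, n_lineages=3, n_branch_events=3, seed=11
    )
    clones = simulate_clone_phylogeny(config, genome)
    intervals = []
    for leaf in leaf_clones(clones):
        for e in leaf.events:
            intervals.append((e.chrom, e.start_bp, e.end_bp, e))
    seen = set()
    for chrom, s, e, ev in intervals:
        for chrom2, s2, e2, ev2 in intervals:
            if ev is ev2 or chrom != chrom2:
                continue
            if s < e2 and s2 < e:
                assert ev == ev2, "distinct events overlap"
    _ = seen


def test_genome_too_small_raises():
    tiny = GenomeModel.default(120)
    config = SimulationConfig(n_trunk_events=40, n_lineages=4, n_branch_events=40)
    with pytest.raises(ValueError, match="too small"):
        simulate_clone_phylogeny(config, tiny)


# ---------------------------------------------------------------------------
# selection dynamics
# ---------------------------------------------------------------------------

def cells_one_quadrant(fractions, cellularity=0.6):
    return {(1, 0): CellTruth(True, cellularity, dict(fractions))}


def test_survival_one_is_identity():
    cells = cells_one_quadrant({"a": 0.8, "b": 0.2})
    out = evolve_fractions(cells, {"a": 1.0, "b": 1.0}, week=5)
    cell = out[(1, 5)]
    assert cell.cellularity == pytest.approx(0.6)
    assert cell.clone_fractions == pytest.approx({"a": 0.8, "b": 0.2})


def test_total_clearance_of_dominant_leaves_minor_clone_alone():
    cells = cells_one_quadrant({"a": 0.8, "b": 0.2})
    out = evolve_fractions(cells, {"a": 0.0, "b": 1.0}, week=5)
    cell = out[(1, 5)]
    assert cell.clone_fractions["a"] == 0.0
    assert cell.clone_fractions["b"] == pytest.approx(1.0)
    # tumour compartment shrank to the surviving 20%
    assert cell.cellularity == pytest.approx(0.6 * 0.2 / (0.6 * 0.2 + 0.4))


def test_minor_resistant_clone_dominates_after_treatment():
    """Dominant clone nearly cleared, minor clone partially resistant:
    post-treatment samples are dominated by the formerly minor clone."""
    cells = cells_one_quadrant({"major": 0.9, "minor": 0.1}, cellularity=0.8)
    out = evolve_fractions(cells, {"major": 0.01, "minor": 0.3}, week=2)
    cell = out[(1, 2)]
    assert cell.clone_fractions["minor"] > 0.7
    assert cell.clone_fractions["minor"] > cell.clone_fractions["major"]


def test_survival_must_be_a_fraction():
    with pytest.raises(ValueError):
        evolve_fractions(cells_one_quadrant({"a": 1.0}), {"a": 1.5}, week=5)


def test_clone_below_floor_recorded_undetectable():
    cells = cells_one_quadrant({"a": 1.0}, cellularity=0.5)
    out = evolve_fractions(cells, {"a": 0.05}, week=5)
    assert out[(1, 5)].detectable_clones(0.10) == {}


# ---------------------------------------------------------------------------
# probe rendering: the mixing equation
# ---------------------------------------------------------------------------

def test_pure_stroma_renders_exact_zeros(genome):
    case = simulate_case(
        SimulationConfig(seed=3), genome, noise_sd=0.0, cellularity=0.0
    )
    for p in case.profiles:
        assert np.all(p.probes["log2"] == 0.0)


@pytest.mark.parametrize("c,expected", [(1.0, np.log2(1.5)), (0.4, np.log2(1.2))])
def test_single_copy_gain_mixing_levels(genome, c, expected):
    config = SimulationConfig(
        n_trunk_events=1, n_lineages=1, n_branch_events=0, p_gain=1.0,
        p_whole_chr=0.0, seed=13,
    )
    case = simulate_case(config, genome, noise_sd=0.0, cellularity=c)
    [event] = case.trunk_events
    p = next(pr for pr in case.profiles if pr.week == 0)
    sub = p.probes[p.probes["chrom"] == event.chrom]
    inside = sub[(sub["pos"] >= event.start_bp) & (sub["pos"] < event.end_bp)]
    outside = p.probes.drop(inside.index)
    assert np.allclose(inside["log2"], expected)
    assert np.all(outside["log2"] == 0.0)


def test_mixing_monotone_in_copy_number():
    from quadclone.calling import expected_log2

    for c in (0.2, 0.5, 1.0):
        values = [expected_log2(cn, c) for cn in range(6)]
        assert values == sorted(values)


# ---------------------------------------------------------------------------
# fixture round trip
# ---------------------------------------------------------------------------

def test_fixture_round_trip_and_byte_stability(genome, tmp_path):
    config = SimulationConfig(seed=21)
    case = simulate_case(config, genome)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_fixture(case.profiles, case.truth, case.clones, d1)
    case2 = simulate_case(config, genome)
    write_fixture(case2.profiles, case2.truth, case2.clones, d2)
    assert fixture_digest(d1) == fixture_digest(d2)

    profiles, manifest = read_fixture(d1)
    assert len(profiles) == len(case.profiles)
    assert {c["clone_id"] for c in manifest["clones"]} == {
        c.clone_id for c in case.clones
    }
    orig = {p.name: p for p in case.profiles}
    for p in profiles:
        ref = orig[p.name]
        assert np.allclose(p.probes["log2"], ref.probes["log2"], atol=5e-7)
        assert list(p.probes["pos"]) == list(ref.probes["pos"])
        assert p.cellularity == pytest.approx(ref.cellularity)


def test_different_seeds_differ(genome, tmp_path):
    a = simulate_case(SimulationConfig(seed=1), genome)
    b = simulate_case(SimulationConfig(seed=2), genome)
    assert {str(e) for e in a.trunk_events} != {str(e) for e in b.trunk_events}
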