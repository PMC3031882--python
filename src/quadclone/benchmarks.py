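"""Seeded recovery benchmarks: simulate ground-truthed cases, run the
full pipeline, and score how well catalogue, trunk, subpopulation
partition and trajectory classes are recovered.

Used by the test suite and by the reproduction script; all randomness is
controlled by the base seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dynamics import selection_summary, true_trajectories
from .events import AberrationEvent
from .genome import GenomeModel
from .pipeline import CaseResult, PipelineConfig, analyze_profiles
from .synthetic import SimulatedCase, SimulationConfig, leaf_clones, simulate_case

__all__ = ["RecoveryScore", "score_case", "run_recovery_benchmark"]


@dataclass
class RecoveryScore:
    """Per-run recovery scores against simulation truth."""

    catalogue_exact: bool
    trunk_exact: bool
    trunk_recovered: int
    trunk_total: int
    partition_exact: bool
    trajectories_exact: bool

    @property
    def all_exact(self) -> bool:
        return (
            self.catalogue_exact
            and self.trunk_exact
            and self.partition_exact
            and self.trajectories_exact
        )


def _true_partition(case: SimulatedCase) -> set[frozenset]:
    """Partition of truly-detectable samples by dominant lineage."""
    groups: dict[str, set] = {}
    for p in case.profiles:
        lineage = case.true_lineage(p.quadrant, p.week)
        if lineage is not None:
            groups.setdefault(lineage, set()).add(p.sample_key)
    return {frozenset(v) for v in groups.values()}


def _event_recovered(
    truth: AberrationEvent, found: list[AberrationEvent], tol_mb: float
) -> bool:
    return any(
        f.chrom == truth.chrom
        and f.kind == truth.kind
        and abs(f.start.mb - truth.start.mb) <= tol_mb
        and abs(f.end.mb - truth.end.mb) <= tol_mb
        for f in found
    )


def score_case(
    case: SimulatedCase, result: CaseResult, tol_mb: float
) -> RecoveryScore:
    truth_catalogue = set()
    for leaf in leaf_clones(case.clones):
        truth_catalogue |= set(leaf.events)
    found = list(result.matrix.events) if result.matrix else []
    trunk_found = list(result.early.trunk_events) if result.early else []
    trunk = sorted(case.trunk_events, key=str)
    n_rec = sum(_event_recovered(e, trunk_found, tol_mb) for e in trunk)

    inferred_partition = {}
    for s, label in result.labels.items():
        inferred_partition.setdefault(label, set()).add(s)
    partition_exact = (
        {frozenset(v) for v in inferred_partition.values()}
        == _true_partition(case)
    )
    summary = selection_summary(case.truth, result.trajectories)
    return RecoveryScore(
        catalogue_exact=set(found) == truth_catalogue,
        trunk_exact=(
            n_rec == len(trunk)
            and all(_event_recovered(e, trunk, tol_mb) for e in trunk_found)
        ),
        trunk_recovered=n_rec,
        trunk_total=len(trunk),
        partition_exact=partition_exact,
        trajectories_exact=summary["n_correct"] == summary["n_quadrants"],
    )


def run_recovery_benchmark(
    n_runs: int,
    base_seed: int = 0,
    noise_sd: float | None = None,
    cellularity: float | None = None,
    n_probes: int = 4000,
    n_perm: int = 200,
    sim_kwargs: dict | None = None,
) -> dict:
    """Simulate ``n_runs`` cases and score pipeline recovery.

    ``noise_sd``/``cellularity`` override the generator defaults (pass
    0.0 / 1.0 for the noiseless pure-tumour regime).  Returns aggregate
    rates plus the per-run scores.
    """
    genome = GenomeModel.default(n_probes)
    config = PipelineConfig(n_perm=n_perm)
    spacing_mb = genome.probe_spacing_bp("1") / 1e6
    score_tol = max(config.tol_mb, config.tol_probes * spacing_mb)
    scores: list[RecoveryScore] = []
    for i in range(n_runs):
        sim = SimulationConfig(
            seed=(base_seed * 100_003 + i) % (2**31 - 1),
            **(sim_kwargs or {}),
        )
        case = simulate_case(sim, genome, noise_sd=noise_sd, cellularity=cellularity)
        result = analyze_profiles(case.profiles, genome, config)
        scores.append(score_case(case, result, score_tol))
    n = len(scores)
    trunk_total = sum(s.trunk_total for s in scores)
    return {
        "n_runs": n,
        "catalogue_exact_rate": sum(s.catalogue_exact for s in scores) / n,
        "trunk_exact_rate": sum(s.trunk_exact for s in scores) / n,
        "trunk_event_recovery": (
            sum(s.trunk_recovered for s in scores) / trunk_total
            if trunk_total
            else 1.0
        ),
        "partition_match_rate": sum(s.partition_exact for s in scores) / n,
        "trajectory_exact_rate": sum(s.trajectories_exact for s in scores) / n,
        "all_exact_rate": sum(s.all_exact for s in scores) / n,
        "scores": scores,
    }
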