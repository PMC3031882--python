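"""End-to-end analysis: normalise -> segment -> call -> events ->
heterogeneity -> phylogeny -> dynamics, for one case at a time.

Two entry points: :func:`analyze_profiles` starts from probe-level data;
:func:`analyze_matrix` starts from an already-matched event matrix (the
packaged published event table, or any event CSV), skipping segmentation
entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .calling import ProfileStatus, call_segments, flag_abnormal
from .dynamics import SubpopulationMap, TrajectoryCall, build_map, call_trajectories
from .events import EventMatrix, match_events, scaled_tolerance, segments_to_events
from .genome import GenomeModel
from .heterogeneity import (
    CaseVerdict,
    HetCall,
    assign_subpopulations,
    case_verdict,
    classify_hom_het,
)
from .phylogeny import CaseTree, EarlyEventReport, build_tree, infer_early_events
from .preprocessing import ProbeProfile, cbs_segment, median_normalize

log = logging.getLogger("quadclone")

__all__ = ["PipelineConfig", "CaseResult", "analyze_profiles", "analyze_matrix"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, YAML round-trippable."""

    alpha: float = 0.01
    n_perm: int = 10_000
    undo_sd: float = 1.0
    gain_thr: float = 0.2
    loss_thr: float = -0.2
    further_gain_thr: float = 0.8
    min_probes: int = 10
    min_span_mb: float = 2.0
    snap_tol_mb: float = 1.0
    tol_mb: float = 1.0
    # breakpoint uncertainty scales with probe spacing: the effective
    # matching/snapping tolerance is at least this many median probe
    # spacings (irrelevant on dense arrays, essential on sparse grids)
    tol_probes: float = 3.0
    d_split: float = 3.0
    distance_weight: str = "count"
    consensus_threshold: float = 0.5
    verdict_mode: str = "inferred"
    n_probes_genome: int = 4000
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class CaseResult:
    """Everything the pipeline derives for one case."""

    case_id: str
    statuses: list[ProfileStatus]
    segments: dict[tuple[int, int], list] = field(default_factory=dict)
    matrix: EventMatrix | None = None
    het: HetCall | None = None
    labels: dict[tuple[int, int], str] = field(default_factory=dict)
    verdict: CaseVerdict | None = None
    tree: CaseTree | None = None
    early: EarlyEventReport | None = None
    spmap: SubpopulationMap | None = None
    trajectories: TrajectoryCall | None = None


def _finish_case(
    matrix: EventMatrix,
    statuses: list[ProfileStatus],
    config: PipelineConfig,
    result: CaseResult,
) -> CaseResult:
    result.matrix = matrix
    result.het = classify_hom_het(matrix, statuses)
    result.labels = assign_subpopulations(
        matrix, statuses, d_split=config.d_split, weight=config.distance_weight
    )
    if result.labels:
        result.verdict = case_verdict(
            matrix, result.labels, statuses, mode=config.verdict_mode
        )
        result.early = infer_early_events(
            matrix, result.labels, consensus_threshold=config.consensus_threshold
        )
        if matrix.samples:
            result.tree = build_tree(matrix, weight=config.distance_weight)
    weeks = tuple(sorted({s.week for s in statuses}))
    result.spmap = build_map(matrix.case_id, result.labels, statuses, weeks=weeks)
    result.trajectories = call_trajectories(result.spmap)
    log.info(
        "case %s: %d samples (%d aberrant), %d catalogue events, %d labels",
        matrix.case_id,
        len(statuses),
        sum(1 for s in statuses if s.abnormal),
        len(matrix.events),
        len(set(result.labels.values())),
    )
    return result


def analyze_profiles(
    profiles: list[ProbeProfile],
    genome: GenomeModel,
    config: PipelineConfig | None = None,
) -> CaseResult:
    """Full pipeline from probe-level log2 ratios for one case."""
    config = config or PipelineConfig()
    if not profiles:
        raise ValueError("no profiles given")
    case_id = profiles[0].case_id
    if any(p.case_id != case_id for p in profiles):
        raise ValueError("profiles must all belong to one case")

    statuses: list[ProfileStatus] = []
    result = CaseResult(case_id=case_id, statuses=statuses)
    event_lists: dict[tuple[int, int], list] = {}
    snap_tol = scaled_tolerance(genome, config.snap_tol_mb, config.tol_probes)
    tol = scaled_tolerance(genome, config.tol_mb, config.tol_probes)
    for p in profiles:
        norm = median_normalize(p)
        segs = cbs_segment(
            norm, alpha=config.alpha, n_perm=config.n_perm, seed=config.seed,
            undo_sd=config.undo_sd,
        )
        called = call_segments(segs, config.gain_thr, config.loss_thr)
        status = flag_abnormal(
            called, p.case_id, p.quadrant, p.week,
            min_probes=config.min_probes, min_span_mb=config.min_span_mb,
            cellularity=p.cellularity,
        )
        statuses.append(status)
        result.segments[p.sample_key] = called
        if status.abnormal:
            event_lists[p.sample_key] = segments_to_events(
                called, genome,
                further_gain_thr=config.further_gain_thr,
                snap_tol_mb=snap_tol,
                min_probes=config.min_probes,
                min_span_mb=config.min_span_mb,
            )
        log.info(
            "sample %s: %d segments, abnormal=%s",
            p.name, len(segs), status.abnormal,
        )
    matrix = match_events(event_lists, case_id, genome, tol_mb=tol)
    return _finish_case(matrix, statuses, config, result)


def analyze_matrix(
    matrix: EventMatrix,
    statuses: list[ProfileStatus],
    config: PipelineConfig | None = None,
) -> CaseResult:
    """Event-level pipeline (fixture mode): heterogeneity, phylogeny and
    dynamics from an existing per-case event matrix."""
    config = config or PipelineConfig()
    result = CaseResult(case_id=matrix.case_id, statuses=statuses)
    return _finish_case(matrix, statuses, config, result)
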