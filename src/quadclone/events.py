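"""Aberration events in the telomere/centromere coordinate dialect and
cross-sample event matching.

Clinical aCGH reports describe copy-number events with one-decimal-Mb
endpoints anchored to chromosome landmarks ("p tel-13.2", "141.6-q tel",
"Whole chr", "cen-51.5").  This module converts called segments into such
events, and matches events across the samples of one case into a unified
catalogue with a per-sample presence matrix.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np

from .calling import Call, CalledSegment
from .genome import MB, GenomeModel

__all__ = [
    "EventKind",
    "Endpoint",
    "AberrationEvent",
    "EventMatrix",
    "segments_to_events",
    "match_events",
    "pairwise_difference",
    "distance_matrix",
    "parse_position",
]

PTEL = "p tel"
CEN = "cen"
QTEL = "q tel"
_TOKENS = (PTEL, CEN, QTEL)

NORMAL_SAMPLE = "NORMAL"


class EventKind(enum.Enum):
    LOSS = "Loss"
    GAIN = "Gain"
    FURTHER_GAIN = "Further gain"
    AMP = "Amplicon"
    HOMDEL = "Homozygous deletion"

    @property
    def level(self) -> int:
        """Copy-level rank within a direction (gain 1 < further gain 2 <
        amplicon 3; loss 1 < homozygous deletion 2)."""
        return {
            EventKind.LOSS: 1,
            EventKind.HOMDEL: 2,
            EventKind.GAIN: 1,
            EventKind.FURTHER_GAIN: 2,
            EventKind.AMP: 3,
        }[self]


@dataclass(frozen=True)
class Endpoint:
    """One event endpoint: a landmark token or a one-decimal Mb value.

    Equality and hashing use the label only, so endpoints compare
    token-for-token and numerically at the reported 0.1 Mb resolution.
    ``mb`` keeps the resolved coordinate for tolerance-based matching.
    """

    label: str
    mb: float = field(compare=False)

    def __post_init__(self) -> None:
        if self.label not in _TOKENS:
            float(self.label)  # must be numeric otherwise

    @property
    def is_token(self) -> bool:
        return self.label in _TOKENS

    @classmethod
    def token(cls, tok: str, genome: GenomeModel, chrom: str) -> "Endpoint":
        c = genome.chromosome(chrom)
        mb = {PTEL: 0.0, CEN: c.centromere_mb, QTEL: c.length_mb}[tok]
        return cls(label=tok, mb=mb)

    @classmethod
    def numeric(cls, mb: float) -> "Endpoint":
        return cls(label=f"{mb:.1f}", mb=float(mb))


@dataclass(frozen=True)
class AberrationEvent:
    """A typed copy-number event on one chromosome.

    ``start``/``end`` resolve to Mb via the genome model; start < end
    after resolution.  Precise base-pair bounds, when known (synthetic
    truth, segment-derived events), travel along for scoring but do not
    participate in equality.
    """

    chrom: str
    start: Endpoint
    end: Endpoint
    kind: EventKind
    start_bp: int | None = field(default=None, compare=False)
    end_bp: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.start.mb < self.end.mb:
            raise ValueError(
                f"event endpoints must satisfy start < end after resolution "
                f"({self.chrom}: {self.start.label}-{self.end.label})"
            )

    @property
    def level(self) -> int:
        return self.kind.level

    @property
    def span_mb(self) -> float:
        return self.end.mb - self.start.mb

    @property
    def is_whole_chromosome(self) -> bool:
        return self.start.label == PTEL and self.end.label == QTEL

    @property
    def position_label(self) -> str:
        if self.is_whole_chromosome:
            return "Whole chr"
        return f"{self.start.label}-{self.end.label}"

    def __str__(self) -> str:  # Table-style one-liner
        return f"{self.chrom} {self.position_label} {self.kind.value}"


def scaled_tolerance(
    genome: GenomeModel, base_mb: float = 1.0, n_spacings: float = 3.0
) -> float:
    """Resolution-aware tolerance: at least ``base_mb`` (the reporting
    dialect's 0.1-Mb-rounded, ~1 Mb convention) and at least a few probe
    spacings, since breakpoints are only localised to the probe grid."""
    spacing_mb = float(
        np.median([genome.probe_spacing_bp(c) for c in genome.chrom_names])
    ) / 1e6
    return max(base_mb, n_spacings * spacing_mb)


def _endpoint_from_bp(
    bp: int,
    genome: GenomeModel,
    chrom: str,
    snap_tol_mb: float,
    is_start: bool,
) -> Endpoint:
    """Snap a base-pair endpoint to p tel / cen / q tel when close enough.

    An endpoint at the first (last) probe of the chromosome is treated as
    reaching the telomere: the array cannot see beyond its probes.
    """
    c = genome.chromosome(chrom)
    pos = genome.probes[chrom.__str__()]
    mb = bp / MB
    if is_start and (bp <= int(pos[0]) or mb <= snap_tol_mb):
        return Endpoint.token(PTEL, genome, chrom)
    if not is_start and (bp >= int(pos[-1]) + 1 or mb >= c.length_mb - snap_tol_mb):
        return Endpoint.token(QTEL, genome, chrom)
    if abs(mb - c.centromere_mb) <= snap_tol_mb:
        return Endpoint.token(CEN, genome, chrom)
    return Endpoint.numeric(round(mb, 1))


def event_from_bp(
    chrom: str,
    start_bp: int,
    end_bp: int,
    kind: EventKind,
    genome: GenomeModel,
    snap_tol_mb: float = 1.0,
) -> AberrationEvent:
    """Build an event from base-pair bounds, applying landmark snapping."""
    return AberrationEvent(
        chrom=str(chrom),
        start=_endpoint_from_bp(start_bp, genome, str(chrom), snap_tol_mb, True),
        end=_endpoint_from_bp(end_bp, genome, str(chrom), snap_tol_mb, False),
        kind=kind,
        start_bp=int(start_bp),
        end_bp=int(end_bp),
    )


def parse_position(
    chrom: str, text: str, kind: EventKind, genome: GenomeModel
) -> AberrationEvent:
    """Parse a report-dialect position string into an event.

    Accepts "Whole chr", "q arm"/"p arm", and "<a>-<b>" where each side
    is "p tel", "cen", "q tel" or a decimal Mb value.  En-dashes are
    treated as hyphens.
    """
    raw = text.strip().replace("–", "-").lower()
    if raw == "whole chr":
        start, end = PTEL, QTEL
    elif raw == "p arm":
        start, end = PTEL, CEN
    elif raw == "q arm":
        start, end = CEN, QTEL
    else:
        parts = [p.strip() for p in raw.split("-")]
        if len(parts) != 2:
            raise ValueError(f"cannot parse position {text!r}")
        start, end = parts

    def make(side: str) -> Endpoint:
        if side in _TOKENS:
            return Endpoint.token(side, genome, chrom)
        return Endpoint.numeric(float(side))

    return AberrationEvent(chrom=str(chrom), start=make(start), end=make(end), kind=kind)


# ---------------------------------------------------------------------------
# Segment -> event conversion
# ---------------------------------------------------------------------------

def _refined_kind(
    seg: CalledSegment, further_gain_thr: float
) -> EventKind | None:
    if seg.call == Call.NEUTRAL:
        return None
    if seg.call == Call.AMP:
        return EventKind.AMP
    if seg.call == Call.HOMDEL:
        return EventKind.HOMDEL
    if seg.call == Call.LOSS:
        return EventKind.LOSS
    if seg.mean_log2 >= further_gain_thr:
        return EventKind.FURTHER_GAIN
    return EventKind.GAIN


def segments_to_events(
    called_segments: list[CalledSegment],
    genome: GenomeModel,
    further_gain_thr: float = 0.8,
    snap_tol_mb: float = 1.0,
    min_probes: int = 10,
    min_span_mb: float = 2.0,
) -> list[AberrationEvent]:
    """Convert called segments into named events.

    Maximal runs of segments with the same refined kind become one event.
    Gains above ``further_gain_thr`` (log2, roughly a second copy gained
    in pure tumour) become FURTHER_GAIN, so a stepped gain is reported as
    a GAIN with a FURTHER_GAIN on the higher step, matching report
    conventions.  Single-copy gains/losses smaller than ``min_probes`` or
    ``min_span_mb`` are discarded as noise; amplicons and homozygous
    deletions are exempt because they are focal by nature.
    """
    events: list[AberrationEvent] = []
    by_chrom: dict[str, list[CalledSegment]] = {}
    for seg in called_segments:
        c = genome.chromosome(seg.chrom)  # validates chromosome
        if seg.end_bp > c.length_bp or seg.start_bp < 0:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start_bp}-{seg.end_bp} is outside "
                "the chromosome"
            )
        by_chrom.setdefault(seg.chrom, []).append(seg)

    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start_bp)
        for kind, group_iter in itertools.groupby(
            segs, key=lambda s: _refined_kind(s, further_gain_thr)
        ):
            if kind is None:
                continue
            group = list(group_iter)
            n_probes = sum(s.n_probes for s in group)
            start, end = group[0].start_bp, group[-1].end_bp
            if kind in (EventKind.GAIN, EventKind.FURTHER_GAIN, EventKind.LOSS):
                if n_probes < min_probes or (end - start) / MB < min_span_mb:
                    continue
            elif n_probes < 2:
                continue
            events.append(event_from_bp(chrom, start, end, kind, genome, snap_tol_mb))
    return sorted(
        events, key=lambda e: (genome.chrom_index(e.chrom), e.start.mb, e.end.mb)
    )


# ---------------------------------------------------------------------------
# Cross-sample matching
# ---------------------------------------------------------------------------

@dataclass
class EventMatrix:
    """Per-case unified event catalogue with a samples x events presence
    matrix.  Samples are (quadrant, week) keys of aberrant profiles."""

    case_id: str
    events: list[AberrationEvent]
    samples: list[tuple[int, int]]
    presence: np.ndarray  # bool, shape (n_samples, n_events)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.samples), len(self.events)):
            raise ValueError("presence matrix shape mismatch")

    def sample_index(self, sample: tuple[int, int]) -> int:
        return self.samples.index(tuple(sample))

    def row(self, sample: tuple[int, int]) -> np.ndarray:
        return self.presence[self.sample_index(sample)]

    def events_of(self, sample: tuple[int, int]) -> list[AberrationEvent]:
        return [e for e, p in zip(self.events, self.row(sample)) if p]

    def sample_name(self, sample: tuple[int, int]) -> str:
        return f"{self.case_id}_q{sample[0]}_wk{sample[1]}"


def _endpoints_compatible(a: Endpoint, b: Endpoint, tol_mb: float) -> bool:
    if a.is_token or b.is_token:
        return a.label == b.label
    return abs(a.mb - b.mb) <= tol_mb


def _events_match(a: AberrationEvent, b: AberrationEvent, tol_mb: float) -> bool:
    return (
        a.chrom == b.chrom
        and a.kind == b.kind
        and _endpoints_compatible(a.start, b.start, tol_mb)
        and _endpoints_compatible(a.end, b.end, tol_mb)
    )


def match_events(
    event_lists: dict[tuple[int, int], list[AberrationEvent]],
    case_id: str,
    genome: GenomeModel,
    tol_mb: float = 1.0,
) -> EventMatrix:
    """Match events across the samples of one case.

    Two events are the same catalogue entry iff they share chromosome and
    kind (level-aware: a further gain never matches a plain gain) and
    both endpoints agree - token-for-token for landmark endpoints, within
    ``tol_mb`` for numeric ones.  Matching is transitively closed by
    single linkage across samples, so slight breakpoint jitter chains
    into one entry.
    """
    if tol_mb < 0:
        raise ValueError("tol_mb must be >= 0")
    samples = list(event_lists.keys())
    flat: list[tuple[int, AberrationEvent]] = []  # (sample index, event)
    for si, s in enumerate(samples):
        for e in event_lists[s]:
            flat.append((si, e))

    parent = list(range(len(flat)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if _events_match(flat[i][1], flat[j][1], tol_mb):
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(flat)):
        clusters.setdefault(find(i), []).append(i)

    entries: list[tuple[AberrationEvent, set[int]]] = []
    for members in clusters.values():
        evs = [flat[i][1] for i in members]
        mid_start = float(np.median([e.start.mb for e in evs]))
        mid_end = float(np.median([e.end.mb for e in evs]))
        rep = min(
            evs,
            key=lambda e: (
                abs(e.start.mb - mid_start) + abs(e.end.mb - mid_end),
                evs.index(e),
            ),
        )
        entries.append((rep, {flat[i][0] for i in members}))

    entries.sort(
        key=lambda t: (
            genome.chrom_index(t[0].chrom),
            t[0].start.mb,
            t[0].end.mb,
            t[0].kind.value,
        )
    )
    presence = np.zeros((len(samples), len(entries)), dtype=bool)
    for col, (_, present_in) in enumerate(entries):
        for si in present_in:
            presence[si, col] = True
    return EventMatrix(
        case_id=case_id,
        events=[rep for rep, _ in entries],
        samples=samples,
        presence=presence,
    )


def pairwise_difference(
    matrix: EventMatrix,
    sample_a: tuple[int, int],
    sample_b: tuple[int, int],
    weight: str = "count",
) -> float:
    """Distance between two samples' presence rows.

    ``weight='count'`` is the symmetric Hamming distance (number of
    differing events).  ``weight='span'`` weights each differing event by
    its span in Mb, which emphasises arm-level lineage markers over focal
    jitter.
    """
    ra, rb = matrix.row(sample_a), matrix.row(sample_b)
    diff = ra ^ rb
    if weight == "count":
        return float(np.sum(diff))
    if weight == "span":
        return float(sum(e.span_mb for e, d in zip(matrix.events, diff) if d))
    raise ValueError("weight must be 'count' or 'span'")


def directional_difference(
    matrix: EventMatrix, sample_a: tuple[int, int], sample_b: tuple[int, int]
) -> int:
    """Events present in ``sample_a`` but not in ``sample_b``."""
    ra, rb = matrix.row(sample_a), matrix.row(sample_b)
    return int(np.sum(ra & ~rb))


def distance_matrix(
    matrix: EventMatrix,
    include_normal: bool = False,
    weight: str = "count",
) -> tuple[list[str], np.ndarray]:
    """Square distance matrix over samples (optionally plus an all-zero
    diploid NORMAL pseudo-sample)."""
    rows = [matrix.row(s).astype(bool) for s in matrix.samples]
    ids = [matrix.sample_name(s) for s in matrix.samples]
    if include_normal:
        rows.append(np.zeros(len(matrix.events), dtype=bool))
        ids.append(NORMAL_SAMPLE)
    if weight == "count":
        w = np.ones(len(matrix.events))
    elif weight == "span":
        w = np.array([e.span_mb for e in matrix.events])
    else:
        raise ValueError("weight must be 'count' or 'span'")
    n = len(rows)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.sum(w[rows[i] ^ rows[j]]))
            dm[i, j] = dm[j, i] = d
    return ids, dm
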