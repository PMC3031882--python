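"""Copy-number state calling and abnormal-profile bookkeeping.

Amplification and homozygous deletion use the fixed +/-1.5 log2-ratio
definitions conventional for clinical aCGH; single-copy gain and loss
thresholds default to +/-0.2 log2 and are configurable because stromal
dilution compresses the observed ratios (see :func:`expected_log2`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .preprocessing import Segment

__all__ = [
    "Call",
    "CalledSegment",
    "ProfileStatus",
    "call_segments",
    "flag_abnormal",
    "expected_log2",
]

AMP_THRESHOLD = 1.5
HOMDEL_THRESHOLD = -1.5
HOMDEL_FLOOR = -4.0


class Call(enum.IntEnum):
    """Copy-number state, ordered from deepest loss to amplification."""

    HOMDEL = 0
    LOSS = 1
    NEUTRAL = 2
    GAIN = 3
    AMP = 4


@dataclass(frozen=True)
class CalledSegment:
    segment: Segment
    call: Call

    @property
    def chrom(self) -> str:
        return self.segment.chrom

    @property
    def start_bp(self) -> int:
        return self.segment.start_bp

    @property
    def end_bp(self) -> int:
        return self.segment.end_bp

    @property
    def n_probes(self) -> int:
        return self.segment.n_probes

    @property
    def mean_log2(self) -> float:
        return self.segment.mean_log2

    @property
    def span_mb(self) -> float:
        return self.segment.span_mb


@dataclass(frozen=True)
class ProfileStatus:
    """Abnormal/normal verdict for one sample's profile."""

    case_id: str
    quadrant: int
    week: int
    abnormal: bool
    aberrant_fraction: float | None = None
    cellularity: float | None = None

    @property
    def sample_key(self) -> tuple[int, int]:
        return (self.quadrant, self.week)


def call_segments(
    segments: list[Segment],
    gain_thr: float = 0.2,
    loss_thr: float = -0.2,
) -> list[CalledSegment]:
    """Label each segment by its mean log2 ratio.

    AMP (> +1.5) and HOMDEL (< -1.5) are fixed; gain/loss thresholds
    partition the remainder.
    """
    if not loss_thr < 0 < gain_thr < AMP_THRESHOLD:
        raise ValueError("thresholds must satisfy loss_thr < 0 < gain_thr < 1.5")
    called = []
    for seg in segments:
        m = seg.mean_log2
        if m > AMP_THRESHOLD:
            call = Call.AMP
        elif m < HOMDEL_THRESHOLD:
            call = Call.HOMDEL
        elif m > gain_thr:
            call = Call.GAIN
        elif m < loss_thr:
            call = Call.LOSS
        else:
            call = Call.NEUTRAL
        called.append(CalledSegment(segment=seg, call=call))
    return called


def qualifies(seg: CalledSegment, min_probes: int = 10, min_span_mb: float = 2.0) -> bool:
    """Whether a non-neutral segment is large enough to trust.

    Small or probe-poor segments are treated as noise for both the
    abnormal-profile flag and event extraction.
    """
    return (
        seg.call != Call.NEUTRAL
        and seg.n_probes >= min_probes
        and seg.span_mb >= min_span_mb
    )


def flag_abnormal(
    called_segments: list[CalledSegment],
    case_id: str,
    quadrant: int,
    week: int,
    min_probes: int = 10,
    min_span_mb: float = 2.0,
    cellularity: float | None = None,
) -> ProfileStatus:
    """Flag a profile abnormal iff it has at least one qualifying
    non-neutral segment; also report the aberrant autosomal probe
    fraction."""
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    abnormal = any(qualifies(s, min_probes, min_span_mb) for s in called_segments)
    auto = [s for s in called_segments if s.chrom != "X"]
    total = sum(s.n_probes for s in auto)
    aberrant = sum(s.n_probes for s in auto if s.call != Call.NEUTRAL)
    return ProfileStatus(
        case_id=case_id,
        quadrant=quadrant,
        week=week,
        abnormal=abnormal,
        aberrant_fraction=(aberrant / total) if total else None,
        cellularity=cellularity,
    )


def expected_log2(
    cn: float, cellularity: float, floor: float = HOMDEL_FLOOR
) -> float:
    """Expected log2 ratio of a clone at integer copy number ``cn``
    diluted by normal diploid stroma.

    log2((c*cn + (1-c)*2) / 2), floored to avoid -inf at homozygous
    deletions in pure tumour.
    """
    if cn < 0:
        raise ValueError("copy number must be >= 0")
    if not 0 <= cellularity <= 1:
        raise ValueError("cellularity must be in [0, 1]")
    mix = cellularity * cn + (1 - cellularity) * 2.0
    if mix <= 0:
        return floor
    return max(float(np.log2(mix / 2.0)), floor)
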