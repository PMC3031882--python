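"""Subpopulation maps over quadrants and timepoints, and per-quadrant
trajectory calls under treatment selection.

A quadrant's trajectory compares its first and last observed states:
CLEARANCE (tumour genotype replaced by a normal profile), PERSISTENCE
(same subpopulation throughout) or REPLACEMENT (one subpopulation
replaced by another).  Quadrants missing at the end of treatment yield no
call - absence of a biopsy is not evidence of clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calling import ProfileStatus
from .synthetic import SpatialTemporalTruth

__all__ = [
    "NORMAL",
    "MISSING",
    "SubpopulationMap",
    "TrajectoryCall",
    "build_map",
    "call_trajectories",
    "selection_summary",
    "true_trajectories",
]

NORMAL = "NORMAL"
MISSING = "MISSING"
QUADRANTS = (1, 2, 3, 4)

CLEARANCE = "CLEARANCE"
PERSISTENCE = "PERSISTENCE"
REPLACEMENT = "REPLACEMENT"


@dataclass
class SubpopulationMap:
    """Quadrant x week grid of subpopulation labels / NORMAL / MISSING."""

    case_id: str
    weeks: list[int]
    grid: dict[tuple[int, int], str]  # (quadrant, week) -> label/NORMAL/MISSING

    def cell(self, quadrant: int, week: int) -> str:
        return self.grid.get((quadrant, week), MISSING)

    def observed(self, quadrant: int) -> list[tuple[int, str]]:
        """(week, state) for every non-missing cell of the quadrant."""
        return [
            (w, self.grid[(quadrant, w)])
            for w in self.weeks
            if self.grid.get((quadrant, w), MISSING) != MISSING
        ]


@dataclass
class TrajectoryCall:
    case_id: str
    per_quadrant: dict[int, str | None]
    residual_disease_week5: bool
    resistant_label: str | None
    week5_labels: list[str] = field(default_factory=list)
    conflicting_week5: bool = False


def build_map(
    case_id: str,
    labels: dict[tuple[int, int], str],
    statuses: list[ProfileStatus],
    weeks: tuple[int, ...] = (0, 2, 5),
) -> SubpopulationMap:
    """Fill the grid: subpopulation label where a sample is aberrant,
    NORMAL where a sample exists with a normal profile, MISSING where no
    sample was taken."""
    grid: dict[tuple[int, int], str] = {
        (q, w): MISSING for q in QUADRANTS for w in weeks
    }
    for st in statuses:
        if st.week not in weeks:
            continue
        key = st.sample_key
        if st.abnormal:
            grid[key] = labels.get(key, "A")
        else:
            grid[key] = NORMAL
    return SubpopulationMap(case_id=case_id, weeks=list(weeks), grid=grid)


def call_trajectories(spmap: SubpopulationMap) -> TrajectoryCall:
    """Classify each quadrant by its first and last observed states and
    summarise end-of-treatment residual disease."""
    last_week = max(spmap.weeks)
    per_quadrant: dict[int, str | None] = {}
    for q in QUADRANTS:
        seen = spmap.observed(q)
        if len(seen) < 2:
            per_quadrant[q] = None
            continue
        (_, first), (_, last) = seen[0], seen[-1]
        if first == NORMAL:
            per_quadrant[q] = None  # no tumour genotype to track
        elif last == NORMAL:
            per_quadrant[q] = CLEARANCE
        elif first == last:
            per_quadrant[q] = PERSISTENCE
        else:
            per_quadrant[q] = REPLACEMENT

    week5_labels = sorted(
        {
            spmap.cell(q, last_week)
            for q in QUADRANTS
            if spmap.cell(q, last_week) not in (NORMAL, MISSING)
        }
    )
    return TrajectoryCall(
        case_id=spmap.case_id,
        per_quadrant=per_quadrant,
        residual_disease_week5=bool(week5_labels),
        resistant_label=week5_labels[0] if len(week5_labels) == 1 else None,
        week5_labels=week5_labels,
        conflicting_week5=len(week5_labels) > 1,
    )


def true_trajectories(truth: SpatialTemporalTruth) -> dict[int, str | None]:
    """Ground-truth trajectory classes from a simulation truth object,
    using the truth's own detection floor."""
    weeks = truth.weeks()
    out: dict[int, str | None] = {}
    for q in QUADRANTS:
        observed = [
            (w, truth.dominant_clone(q, w))
            for w in weeks
            if (q, w) in truth.cells and truth.cells[(q, w)].present
        ]
        if len(observed) < 2:
            out[q] = None
            continue
        (_, first), (_, last) = observed[0], observed[-1]
        if first is None:
            out[q] = None
        elif last is None:
            out[q] = CLEARANCE
        elif first == last:
            out[q] = PERSISTENCE
        else:
            out[q] = REPLACEMENT
    return out


def selection_summary(
    truth: SpatialTemporalTruth, calls: TrajectoryCall
) -> dict:
    """Confusion counts of called vs true trajectory classes (synthetic
    runs only, where truth is available)."""
    true = true_trajectories(truth)
    confusion: dict[tuple[str, str], int] = {}
    n_called = n_correct = 0
    for q in QUADRANTS:
        t, c = true.get(q), calls.per_quadrant.get(q)
        if t is None and c is None:
            continue
        key = (t or "NONE", c or "NONE")
        confusion[key] = confusion.get(key, 0) + 1
        n_called += 1
        if t == c:
            n_correct += 1
    return {
        "confusion": confusion,
        "n_quadrants": n_called,
        "n_correct": n_correct,
        "accuracy": (n_correct / n_called) if n_called else float("nan"),
    }
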