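"""Homogeneous/heterogeneous event classification and subpopulation
assignment within a case.

Normal-profile samples reflect stromal content, not genotype, so they are
excluded throughout: only samples with an abnormal profile vote on
whether an event is homogeneous, and only they receive subpopulation
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .calling import ProfileStatus
from .events import AberrationEvent, EventMatrix, distance_matrix

__all__ = [
    "HetCall",
    "CaseVerdict",
    "classify_hom_het",
    "assign_subpopulations",
    "case_verdict",
    "consensus_genotypes",
]


@dataclass
class HetCall:
    """Per-event homogeneous/heterogeneous status for one case."""

    case_id: str
    status: dict[AberrationEvent, str]  # "HOM" | "HET"
    present_in: dict[AberrationEvent, list[tuple[int, int]]]
    no_tumour_profile: bool = False

    @property
    def hom_events(self) -> list[AberrationEvent]:
        return [e for e, s in self.status.items() if s == "HOM"]

    @property
    def het_events(self) -> list[AberrationEvent]:
        return [e for e, s in self.status.items() if s == "HET"]


@dataclass
class CaseVerdict:
    case_id: str
    n_subpopulations_week0: int
    n_subpopulations_ever: int
    heterogeneous: bool
    monoclonal_support: list[AberrationEvent]


def _aberrant_samples(
    matrix: EventMatrix, statuses: list[ProfileStatus]
) -> list[tuple[int, int]]:
    by_key = {s.sample_key: s for s in statuses}
    out = []
    for sample in matrix.samples:
        st = by_key.get(sample)
        if st is None or st.abnormal:
            out.append(sample)
    return out


def classify_hom_het(
    matrix: EventMatrix, statuses: list[ProfileStatus]
) -> HetCall:
    """An event is HOM iff present in every aberrant sample of the case,
    across all quadrants and timepoints; HET otherwise."""
    aberrant = _aberrant_samples(matrix, statuses)
    if not aberrant:
        return HetCall(
            case_id=matrix.case_id, status={}, present_in={},
            no_tumour_profile=True,
        )
    status: dict[AberrationEvent, str] = {}
    present_in: dict[AberrationEvent, list[tuple[int, int]]] = {}
    for col, event in enumerate(matrix.events):
        carriers = [s for s in aberrant if matrix.presence[matrix.sample_index(s), col]]
        present_in[event] = carriers
        status[event] = "HOM" if len(carriers) == len(aberrant) else "HET"
    return HetCall(case_id=matrix.case_id, status=status, present_in=present_in)


def assign_subpopulations(
    matrix: EventMatrix,
    statuses: list[ProfileStatus],
    d_split: float = 3.0,
    weight: str = "count",
) -> dict[tuple[int, int], str]:
    """Cluster aberrant samples into genetic subpopulations.

    Average-linkage hierarchical clustering under the event distance; the
    dendrogram is cut at the largest merge-height gap, provided the
    resulting between-cluster separation is at least ``d_split`` (in
    events, or Mb for ``weight='span'``) - smaller differences count as
    subclonal variation within one population.  Labels 'A', 'B', ... are
    ordered by week-0 sample count, then by first appearance.
    """
    aberrant = _aberrant_samples(matrix, statuses)
    if not aberrant:
        return {}
    if len(aberrant) == 1:
        return {aberrant[0]: "A"}

    sub = EventMatrix(
        case_id=matrix.case_id,
        events=matrix.events,
        samples=aberrant,
        presence=np.vstack([matrix.row(s) for s in aberrant]),
    )
    _, dm = distance_matrix(sub, include_normal=False, weight=weight)
    z = linkage(squareform(dm, checks=False), method="average")
    heights = np.concatenate([[0.0], z[:, 2]])
    gaps = np.diff(heights)
    k = int(np.argmax(gaps[::-1]))  # ties -> prefer the higher cut
    k = len(gaps) - 1 - k
    if heights[k + 1] < d_split or gaps[k] <= 0:
        assignment = np.ones(len(aberrant), dtype=int)
    else:
        cut = (heights[k] + heights[k + 1]) / 2.0
        assignment = fcluster(z, t=cut, criterion="distance")

    clusters: dict[int, list[tuple[int, int]]] = {}
    for sample, c in zip(aberrant, assignment):
        clusters.setdefault(int(c), []).append(sample)

    def order_key(c: int) -> tuple:
        members = clusters[c]
        n_week0 = sum(1 for q, w in members if w == 0)
        first = min(aberrant.index(m) for m in members)
        return (-n_week0, first)

    labels = {}
    for rank, c in enumerate(sorted(clusters, key=order_key)):
        for sample in clusters[c]:
            labels[sample] = chr(ord("A") + rank)
    return labels


def consensus_genotypes(
    matrix: EventMatrix,
    labels: dict[tuple[int, int], str],
    threshold: float = 1.0,
) -> dict[str, frozenset[AberrationEvent]]:
    """Consensus event set per subpopulation label: events present in at
    least ``threshold`` of the label's samples (1.0 = in every sample)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out: dict[str, frozenset[AberrationEvent]] = {}
    for label in sorted(set(labels.values())):
        members = [s for s, l in labels.items() if l == label]
        rows = np.vstack([matrix.row(s) for s in members])
        frac = rows.mean(axis=0)
        out[label] = frozenset(
            e for e, f in zip(matrix.events, frac) if f >= threshold - 1e-12
        )
    return out


def case_verdict(
    matrix: EventMatrix,
    labels: dict[tuple[int, int], str],
    statuses: list[ProfileStatus],
    mode: str = "inferred",
) -> CaseVerdict:
    """Case-level heterogeneity verdict.

    ``mode='week0'`` counts only subpopulations observed pre-treatment.
    ``mode='inferred'`` (default) counts every subpopulation ever
    observed: under perfect phylogeny a distinct genotype appearing during
    treatment cannot have arisen de novo at detectable levels within
    weeks, so it is inferred to have pre-existed below detection.
    """
    if mode not in ("inferred", "week0"):
        raise ValueError("mode must be 'inferred' or 'week0'")
    week0 = {l for (q, w), l in labels.items() if w == 0}
    ever = set(labels.values())
    n = len(week0) if mode == "week0" else len(ever)
    het = classify_hom_het(matrix, statuses)
    return CaseVerdict(
        case_id=matrix.case_id,
        n_subpopulations_week0=len(week0),
        n_subpopulations_ever=len(ever),
        heterogeneous=n >= 2,
        monoclonal_support=het.hom_events,
    )
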