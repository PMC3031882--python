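"""Per-case phylogeny over sample genotypes and early-event inference.

Trees are built by neighbour joining on the event distance between
samples, with an artificial diploid NORMAL genome included as outgroup so
branch lengths read as numbers of copy-number events from the germline
state.  Under perfect phylogeny and complete detection the event distance
is additive on the true clone tree, so NJ recovers both topology and
branch lengths exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .events import (
    NORMAL_SAMPLE,
    AberrationEvent,
    EventMatrix,
    distance_matrix,
)
from .heterogeneity import consensus_genotypes

__all__ = [
    "CaseTree",
    "EarlyEventReport",
    "build_tree",
    "infer_early_events",
    "order_chromosome_events",
]


@dataclass
class CaseTree:
    """NJ tree over aberrant samples plus the diploid NORMAL outgroup."""

    case_id: str
    tree: TreeNode  # unrooted (trifurcating root as produced by NJ)
    leaf_ids: list[str]

    def rooted_at_normal(self) -> TreeNode:
        """View rooted on the NORMAL leaf's edge, for display."""
        normal = self.tree.find(NORMAL_SAMPLE)
        rooted = self.tree.root_at(normal.parent)
        return rooted

    def newick(self) -> str:
        return str(self.rooted_at_normal()).strip()

    def tip_distance(self, a: str, b: str) -> float:
        return float(self.tree.find(a).distance(self.tree.find(b)))

    def clade_tips(self, tips: list[str]) -> bool:
        """True if ``tips`` form a clade when rooted at NORMAL."""
        rooted = self.rooted_at_normal()
        nodes = [rooted.find(t) for t in tips]
        lca = rooted.lowest_common_ancestor(nodes) if len(nodes) > 1 else nodes[0]
        found = {t.name for t in lca.tips()} if not lca.is_tip() else {lca.name}
        return found == set(tips)


@dataclass
class EarlyEventReport:
    """Trunk (pre-divergence) vs branch event classification."""

    case_id: str
    trunk_events: list[AberrationEvent]
    order_class: dict[AberrationEvent, str]  # "TRUNK" | "BRANCH"
    empty_trunk_warning: bool = False

    @property
    def branch_events(self) -> list[AberrationEvent]:
        return [e for e, c in self.order_class.items() if c == "BRANCH"]


def _clamp_negative_branches(tree: TreeNode) -> None:
    """Clamp negative NJ branch lengths to zero, transferring the deficit
    to the sibling branch so leaf-to-leaf path lengths are preserved as
    far as possible."""
    for node in list(tree.postorder()):
        if node.length is not None and node.length < 0:
            deficit = node.length
            node.length = 0.0
            siblings = [s for s in node.siblings() if s.length is not None]
            if siblings:
                share = deficit / len(siblings)
                for s in siblings:
                    s.length += share


def build_tree(matrix: EventMatrix, weight: str = "count") -> CaseTree:
    """Neighbour-joining tree over the case's samples plus NORMAL.

    Distances are the symmetric event differences between presence rows;
    the NORMAL pseudo-sample carries no events.
    """
    ids, dm = distance_matrix(matrix, include_normal=True, weight=weight)
    if len(ids) < 3:
        if len(ids) < 2:
            raise ValueError("need at least two leaves including NORMAL")
        # two leaves: a single edge; represent as a cherry
        tree = TreeNode.read([f"({ids[0]}:{dm[0, 1] / 2},{ids[1]}:{dm[0, 1] / 2});"])
    else:
        tree = nj(DistanceMatrix(dm, ids=ids), neg_as_zero=False)
        _clamp_negative_branches(tree)
    return CaseTree(case_id=matrix.case_id, tree=tree, leaf_ids=ids)


def infer_early_events(
    matrix: EventMatrix,
    labels: dict[tuple[int, int], str],
    consensus_threshold: float = 0.5,
) -> EarlyEventReport:
    """Trunk events: changes common to all subpopulations of the tumour.

    Each subpopulation is summarised by its consensus genotype (events in
    at least ``consensus_threshold`` of the label's samples - the default
    half tolerates detection dropout in individual low-cellularity
    samples); the trunk is the intersection of the consensus genotypes,
    every other event is a branch event.  An empty trunk would contradict
    a monoclonal origin and is flagged.
    """
    if not labels:
        raise ValueError("at least one subpopulation is required")
    consensus = consensus_genotypes(matrix, labels, threshold=consensus_threshold)
    genotype_sets = list(consensus.values())
    trunk = set(genotype_sets[0])
    for g in genotype_sets[1:]:
        trunk &= g
    order = {
        e: ("TRUNK" if e in trunk else "BRANCH") for e in matrix.events
    }
    trunk_sorted = [e for e in matrix.events if e in trunk]
    return EarlyEventReport(
        case_id=matrix.case_id,
        trunk_events=trunk_sorted,
        order_class=order,
        empty_trunk_warning=len(trunk_sorted) == 0,
    )


def order_chromosome_events(
    report: EarlyEventReport,
    matrix: EventMatrix,
    labels: dict[tuple[int, int], str],
    chrom: str,
) -> list[dict]:
    """Partial-order narrative for one chromosome: which events preceded
    subpopulation divergence (TRUNK) and which followed it, per lineage.

    This is a re-projection of the early-event report onto one
    chromosome; each row lists the event, its order class and the labels
    of the subpopulations carrying it.
    """
    chrom = str(chrom)
    rows = []
    for col, event in enumerate(matrix.events):
        if event.chrom != chrom:
            continue
        carriers = sorted(
            {
                labels[s]
                for s in matrix.samples
                if s in labels and matrix.presence[matrix.sample_index(s), col]
            }
        )
        rows.append(
            {
                "event": event,
                "order": report.order_class[event],
                "lineages": carriers,
            }
        )
    rows.sort(key=lambda r: (0 if r["order"] == "TRUNK" else 1, r["event"].start.mb))
    return rows
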