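"""Ground-truthed simulation of multi-quadrant, multi-timepoint aCGH data.

The generator emulates the biology the downstream analysis assumes: a
monoclonal tumour whose subpopulations diverged from a single ancestor
(perfect phylogeny - every event arises once and is never lost), spatial
structure in which each cervix quadrant is dominated by one lineage,
chemoradiotherapy selection acting multiplicatively on clone fractions,
stromal dilution of the copy-number signal, and i.i.d. Gaussian probe
noise.  Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import HOMDEL_FLOOR
from .events import AberrationEvent, EventKind, event_from_bp, scaled_tolerance
from .genome import MB, GenomeModel
from .preprocessing import ProbeProfile

__all__ = [
    "SimulationConfig",
    "CloneGenotype",
    "CellTruth",
    "SpatialTemporalTruth",
    "simulate_clone_phylogeny",
    "evolve_fractions",
    "render_probe_data",
    "write_fixture",
    "read_fixture",
    "simulate_case",
    "SimulatedCase",
]

ROOT = "ROOT"
QUADRANTS = (1, 2, 3, 4)

COPY_NUMBER = {
    EventKind.GAIN: 3,
    EventKind.FURTHER_GAIN: 4,
    EventKind.AMP: 6,
    EventKind.LOSS: 1,
    EventKind.HOMDEL: 0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for one simulated case.

    Defaults describe a two-lineage heterogeneous tumour: a handful of
    trunk events shared by all cells, private branch events per lineage,
    biopsy cellularity in the range where aberrations are detectable,
    and strong selection that clears the sensitive lineage while the
    resistant one persists through five weeks of chemoradiotherapy.
    """

    n_trunk_events: int = 3
    n_lineages: int = 2
    n_branch_events: int = 4
    survival: tuple[float, ...] | None = None  # per lineage; default set below
    cellularity_range: tuple[float, float] = (0.4, 0.9)
    noise_sd: float = 0.15
    detect_floor: float = 0.10
    min_event_probes: int = 20
    p_whole_chr: float = 0.05
    p_gain: float = 0.5
    weeks: tuple[int, ...] = (0, 5)
    seed: int = 0
    case_id: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.n_trunk_events < 0 or self.n_branch_events < 0:
            raise ValueError("event counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for f in (*self.cellularity_range, self.detect_floor, self.p_gain,
                  self.p_whole_chr):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.survival is not None:
            if len(self.survival) != self.n_lineages:
                raise ValueError("survival needs one entry per lineage")
            if any(not 0 <= s <= 1 for s in self.survival):
                raise ValueError("survival fractions must be in [0, 1]")

    @property
    def lineage_survival(self) -> tuple[float, ...]:
        """Per-lineage survival through the full course of chemo-RT.

        Default: the last lineage is intrinsically resistant (survival 1)
        and all others are sensitive and respond completely (survival
        0.01, which keeps the residual sensitive fraction below the
        detection floor across the whole default cellularity range)."""
        if self.survival is not None:
            return self.survival
        if self.n_lineages == 1:
            return (0.01,)
        return (0.01,) * (self.n_lineages - 1) + (1.0,)


@dataclass(frozen=True)
class CloneGenotype:
    """A clone as the set of events on a diploid baseline.

    Perfect phylogeny: a clone's events always include all of its
    parent's events (no event loss, no parallel gain)."""

    clone_id: str
    parent: str
    events: frozenset[AberrationEvent]

    def copy_number(self, genome: GenomeModel) -> dict[str, np.ndarray]:
        """Integer copy number at every probe."""
        cn = {c: np.full(len(genome.probes[c]), 2, dtype=int)
              for c in genome.chrom_names}
        for ev in self.events:
            pos = genome.probes[ev.chrom]
            lo = np.searchsorted(pos, ev.start_bp, side="left")
            hi = np.searchsorted(pos, ev.end_bp, side="left")
            cn[ev.chrom][lo:hi] = COPY_NUMBER[ev.kind]
        return cn


@dataclass
class CellTruth:
    """Ground truth for one (quadrant, week) biopsy site."""

    present: bool
    cellularity: float
    clone_fractions: dict[str, float]  # fractions of the tumour compartment

    def total_tumour_fraction(self) -> float:
        return self.cellularity * sum(self.clone_fractions.values())

    def detectable_clones(self, floor: float) -> dict[str, float]:
        """Clones whose fraction of all cells reaches the detection floor."""
        return {
            cid: f
            for cid, f in self.clone_fractions.items()
            if self.cellularity * f >= floor
        }


@dataclass
class SpatialTemporalTruth:
    """Quadrant x week grid of clone mixtures with a detection floor."""

    cells: dict[tuple[int, int], CellTruth]
    detect_floor: float = 0.10

    def weeks(self) -> list[int]:
        return sorted({w for _, w in self.cells})

    def dominant_clone(self, quadrant: int, week: int) -> str | None:
        cell = self.cells.get((quadrant, week))
        if cell is None or not cell.present:
            return None
        det = cell.detectable_clones(self.detect_floor)
        if not det:
            return None
        return max(det, key=lambda c: (det[c], c))


# ---------------------------------------------------------------------------
# Clone phylogeny simulation
# ---------------------------------------------------------------------------

def _place_event(
    genome: GenomeModel,
    rng: np.random.Generator,
    taken: dict[str, list[tuple[int, int]]],
    min_probes: int,
    p_whole_chr: float,
    p_gain: float,
    pad_probes: int = 5,
    max_tries: int = 500,
) -> AberrationEvent:
    """Sample one event uniformly over arms, with log-uniform length
    between ~2 Mb and the whole arm, avoiding already-used intervals.

    A padding of a few probes is kept between events so that distinct
    events never fuse into a single segment in any genotype.
    """
    arms = [
        (c.name, arm, lo, hi)
        for c in genome.chromosomes
        for arm, lo, hi in c.arms()
    ]
    for _ in range(max_tries):
        kind = EventKind.GAIN if rng.random() < p_gain else EventKind.LOSS
        if rng.random() < p_whole_chr:
            chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
            pos = genome.probes[chrom]
            lo_i, hi_i = 0, len(pos)
        else:
            chrom, _, lo, hi = arms[rng.integers(len(arms))]
            pos = genome.probes[chrom]
            a = int(np.searchsorted(pos, lo, side="left"))
            b = int(np.searchsorted(pos, hi, side="left"))
            k = b - a
            spacing = genome.probe_spacing_bp(chrom)
            m_min = max(min_probes, int(np.ceil(2 * MB / spacing)), 2)
            if k < m_min:
                continue
            m = int(round(np.exp(rng.uniform(np.log(m_min), np.log(k)))))
            m = min(max(m, m_min), k)
            start_i = a + int(rng.integers(0, k - m + 1))
            lo_i, hi_i = start_i, start_i + m
        if hi_i - lo_i < max(min_probes, 2):
            continue
        start_bp, end_bp = int(pos[lo_i]), int(pos[hi_i - 1]) + 1
        pad = int(pad_probes * genome.probe_spacing_bp(chrom))
        clash = any(
            start_bp - pad < e and s < end_bp + pad
            for s, e in taken.get(chrom, [])
        )
        if clash:
            continue
        taken.setdefault(chrom, []).append((start_bp, end_bp))
        # truth events use the same resolution-aware landmark snapping as
        # the analysis, so recovered catalogues are comparable label-wise
        return event_from_bp(
            chrom, start_bp, end_bp, kind, genome,
            snap_tol_mb=scaled_tolerance(genome),
        )
    raise ValueError(
        "genome too small to place the requested non-overlapping events"
    )


def simulate_clone_phylogeny(
    config: SimulationConfig, genome: GenomeModel
) -> list[CloneGenotype]:
    """Simulate a rooted clone tree: a trunk ancestor plus one leaf clone
    per lineage, each with private branch events on intervals disjoint
    from every other event (perfect phylogeny by construction).

    Returns [root, leaf_1, ..., leaf_n]; event endpoints are snapped to
    probe positions.
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 101])
    taken: dict[str, list[tuple[int, int]]] = {}
    trunk = frozenset(
        _place_event(genome, rng, taken, config.min_event_probes,
                     config.p_whole_chr, config.p_gain)
        for _ in range(config.n_trunk_events)
    )
    root = CloneGenotype(clone_id="trunk", parent=ROOT, events=trunk)
    clones = [root]
    for k in range(config.n_lineages):
        branch = frozenset(
            _place_event(genome, rng, taken, config.min_event_probes,
                         config.p_whole_chr, config.p_gain)
            for _ in range(config.n_branch_events)
        )
        clones.append(
            CloneGenotype(
                clone_id=f"clone{k + 1}",
                parent=root.clone_id,
                events=trunk | branch,
            )
        )
    return clones


def leaf_clones(clones: list[CloneGenotype]) -> list[CloneGenotype]:
    parents = {c.parent for c in clones}
    return [c for c in clones if c.clone_id not in parents]


# ---------------------------------------------------------------------------
# Spatial-temporal truth
# ---------------------------------------------------------------------------

def _week0_truth(
    config: SimulationConfig, leaves: list[CloneGenotype], rng: np.random.Generator
) -> dict[tuple[int, int], CellTruth]:
    cells = {}
    for q in QUADRANTS:
        lineage = (q - 1) * len(leaves) // len(QUADRANTS)
        c = rng.uniform(*config.cellularity_range)
        cells[(q, 0)] = CellTruth(
            present=True,
            cellularity=float(c),
            clone_fractions={leaves[lineage].clone_id: 1.0},
        )
    return cells


def evolve_fractions(
    cells_week0: dict[tuple[int, int], CellTruth],
    survival: dict[str, float],
    week: int,
) -> dict[tuple[int, int], CellTruth]:
    """Apply per-clone survival to every quadrant's week-0 mixture.

    Each clone's cell count is multiplied by its survival fraction while
    the stromal compartment is unchanged, so cellularity shrinks to
    c*T / (c*T + 1 - c) with T the tumour-weighted mean survival, and
    clone fractions renormalise within the residual tumour.
    """
    if any(not 0 <= s <= 1 for s in survival.values()):
        raise ValueError("survival fractions must be in [0, 1]")
    out = {}
    for (q, _w0), cell in cells_week0.items():
        scaled = {
            cid: f * survival.get(cid, 1.0)
            for cid, f in cell.clone_fractions.items()
        }
        t = sum(scaled.values())
        c = cell.cellularity
        denom = c * t + (1 - c)
        new_c = (c * t / denom) if denom > 0 else 0.0
        fractions = {cid: v / t for cid, v in scaled.items() if t > 0}
        out[(q, week)] = CellTruth(
            present=cell.present, cellularity=float(new_c),
            clone_fractions=fractions,
        )
    return out


def build_truth(
    config: SimulationConfig, clones: list[CloneGenotype]
) -> SpatialTemporalTruth:
    leaves = leaf_clones(clones)
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 202])
    week0 = _week0_truth(config, leaves, rng)
    survival = {
        leaf.clone_id: s
        for leaf, s in zip(leaves, config.lineage_survival)
    }
    cells: dict[tuple[int, int], CellTruth] = {}
    for week in config.weeks:
        if week == 0:
            cells.update(week0)
        else:
            # survival is calibrated to the full 5-week course; partial
            # courses act proportionally in time on the log scale
            frac = week / 5.0
            partial = {c: s**frac for c, s in survival.items()}
            cells.update(evolve_fractions(week0, partial, week))
    return SpatialTemporalTruth(cells=cells, detect_floor=config.detect_floor)


# ---------------------------------------------------------------------------
# Probe-level rendering
# ---------------------------------------------------------------------------

def render_probe_data(
    truth: SpatialTemporalTruth,
    clones: list[CloneGenotype],
    genome: GenomeModel,
    noise_sd: float,
    seed: int,
    case_id: str = "SIM",
) -> list[ProbeProfile]:
    """Render each sampled (quadrant, week) into probe-level log2 ratios.

    log2 ratio = log2((c * sum_i f_i cn_i + (1-c) * 2) / 2) + N(0, sd^2),
    floored at the homozygous-deletion floor; deterministic given seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    cn_by_clone = {c.clone_id: c.copy_number(genome) for c in clones}
    profiles = []
    for (q, w), cell in sorted(truth.cells.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if not cell.present:
            continue
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 303, q, w])
        rows = []
        c = cell.cellularity
        for chrom in genome.chrom_names:
            pos = genome.probes[chrom]
            mix = np.full(len(pos), (1 - c) * 2.0)
            for cid, f in cell.clone_fractions.items():
                mix += c * f * cn_by_clone[cid][chrom]
            # any residual tumour mass not covered by listed clones is
            # treated as diploid (normal tissue within the tumour bed)
            residual = 1.0 - sum(cell.clone_fractions.values())
            if residual > 0:
                mix += c * residual * 2.0
            with np.errstate(divide="ignore"):
                log2 = np.log2(mix / 2.0)
            log2 = np.maximum(log2, HOMDEL_FLOOR)
            if noise_sd > 0:
                log2 = log2 + rng.normal(0.0, noise_sd, size=len(pos))
            rows.append(
                pd.DataFrame(
                    {
                        "probe_id": [f"p_{chrom}_{i}" for i in range(len(pos))],
                        "chrom": chrom,
                        "pos": pos,
                        "log2": log2,
                    }
                )
            )
        profiles.append(
            ProbeProfile(
                case_id=case_id,
                quadrant=q,
                week=w,
                probes=pd.concat(rows, ignore_index=True),
                cellularity=float(cell.cellularity),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Fixture round trip
# ---------------------------------------------------------------------------

def _event_to_dict(e: AberrationEvent) -> dict:
    return {
        "chrom": e.chrom,
        "start_label": e.start.label,
        "end_label": e.end.label,
        "start_mb": e.start.mb,
        "end_mb": e.end.mb,
        "kind": e.kind.name,
        "start_bp": e.start_bp,
        "end_bp": e.end_bp,
    }


def write_fixture(
    profiles: list[ProbeProfile],
    truth: SpatialTemporalTruth,
    clones: list[CloneGenotype],
    directory: str | Path,
) -> list[Path]:
    """Write probe tables plus a JSON truth manifest; byte-stable for a
    fixed simulation seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for p in profiles:
        path = directory / f"{p.case_id}_{p.quadrant}_wk{p.week}.tsv"
        df = p.probes.copy()
        df["log2"] = [f"{v:.6f}" for v in df["log2"]]
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    manifest = {
        "detect_floor": truth.detect_floor,
        "clones": [
            {
                "clone_id": c.clone_id,
                "parent": c.parent,
                "events": sorted(
                    (_event_to_dict(e) for e in c.events),
                    key=lambda d: (d["chrom"], d["start_mb"], d["end_mb"]),
                ),
            }
            for c in clones
        ],
        "cells": [
            {
                "quadrant": q,
                "week": w,
                "present": cell.present,
                "cellularity": round(cell.cellularity, 10),
                "clone_fractions": {
                    k: round(v, 10) for k, v in sorted(cell.clone_fractions.items())
                },
            }
            for (q, w), cell in sorted(truth.cells.items())
        ],
    }
    mpath = directory / "truth.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


def read_fixture(directory: str | Path) -> tuple[list[ProbeProfile], dict]:
    """Read back a written fixture: probe profiles plus the raw manifest."""
    directory = Path(directory)
    manifest = json.loads((directory / "truth.json").read_text())
    cellularity = {
        (c["quadrant"], c["week"]): c["cellularity"] for c in manifest["cells"]
    }
    profiles = []
    for path in sorted(directory.glob("*_wk*.tsv")):
        case_id, quadrant, wk = path.stem.rsplit("_", 2)
        q, w = int(quadrant), int(wk.removeprefix("wk"))
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        profiles.append(
            ProbeProfile(
                case_id=case_id, quadrant=q, week=w, probes=df,
                cellularity=cellularity.get((q, w)),
            )
        )
    return profiles, manifest


def fixture_digest(directory: str | Path) -> str:
    h = hashlib.sha256()
    for path in sorted(Path(directory).iterdir()):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class SimulatedCase:
    """Everything one simulated case produces."""

    config: SimulationConfig
    genome: GenomeModel
    clones: list[CloneGenotype]
    truth: SpatialTemporalTruth
    profiles: list[ProbeProfile]

    @property
    def trunk_events(self) -> frozenset[AberrationEvent]:
        return next(c for c in self.clones if c.parent == ROOT).events

    def true_lineage(self, quadrant: int, week: int) -> str | None:
        return self.truth.dominant_clone(quadrant, week)


def simulate_case(
    config: SimulationConfig,
    genome: GenomeModel | None = None,
    noise_sd: float | None = None,
    cellularity: float | None = None,
) -> SimulatedCase:
    """One-call simulation: clone tree, spatial/temporal truth, rendered
    probe profiles.  ``noise_sd``/``cellularity`` override the config for
    noiseless or fixed-purity scenarios."""
    if genome is None:
        genome = GenomeModel.default()
    if cellularity is not None:
        config = SimulationConfig(
            **{**asdict(config), "cellularity_range": (cellularity, cellularity)}
        )
    clones = simulate_clone_phylogeny(config, genome)
    truth = build_truth(config, clones)
    sd = config.noise_sd if noise_sd is None else noise_sd
    profiles = render_probe_data(
        truth, clones, genome, sd, config.seed, case_id=config.case_id
    )
    return SimulatedCase(
        config=config, genome=genome, clones=clones, truth=truth, profiles=profiles
    )
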