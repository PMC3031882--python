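"""File formats, packaged study fixtures and cohort bookkeeping.

Formats: probe tables (TSV), SEG, BED (0-based half-open), Newick, and
CSV/JSON reports.  The packaged fixtures are machine-readable
transcriptions of the study's published per-sample profile flags
(clinical table) and per-case aberration-event table, which serve as the
canonical event-level inputs when raw arrays are not available.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import Call, CalledSegment, ProfileStatus
from .events import AberrationEvent, EventKind, EventMatrix, parse_position
from .genome import GenomeModel
from .preprocessing import ProbeProfile, Segment

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "write_seg",
    "write_bed",
    "write_newick",
    "write_event_csv",
    "load_table1_samples",
    "load_table1_clinical",
    "load_table2_matrices",
    "load_recruitment",
    "cohort_filter",
    "fixture_path",
]

PROBE_COLUMNS = ["probe_id", "chrom", "pos_bp", "log2_ratio"]

KIND_BY_NAME = {k.value: k for k in EventKind}


# ---------------------------------------------------------------------------
# Probe tables
# ---------------------------------------------------------------------------

def read_probe_table(
    path: str | Path,
    case_id: str | None = None,
    quadrant: int | None = None,
    week: int | None = None,
    cellularity: float | None = None,
) -> ProbeProfile:
    """Read a tab-delimited probe table (probe_id, chrom, pos_bp,
    log2_ratio).  Metadata defaults are parsed from a
    ``<case>_<quadrant>_wk<week>`` file name."""
    path = Path(path)
    if case_id is None or quadrant is None or week is None:
        try:
            stem_case, q, wk = path.stem.rsplit("_", 2)
            case_id = case_id or stem_case
            quadrant = quadrant if quadrant is not None else int(q)
            week = week if week is not None else int(wk.removeprefix("wk"))
        except (ValueError, IndexError) as exc:
            raise ValueError(
                f"cannot infer sample metadata from file name {path.name!r}; "
                "pass case_id/quadrant/week explicitly"
            ) from exc
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"malformed probe table {path}: {exc}") from exc
    rename = {"pos_bp": "pos", "log2_ratio": "log2"}
    df = df.rename(columns=rename)
    missing = {"probe_id", "chrom", "pos", "log2"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: probe table lacks columns {sorted(missing)}"
        )
    values = pd.to_numeric(df["log2"], errors="coerce").to_numpy(dtype=float)
    bad = df.index[~np.isfinite(values)].tolist()
    if bad:
        raise ValueError(
            f"{path}: non-numeric log2 ratio at line(s) "
            f"{[i + 2 for i in bad[:5]]}"
        )
    df["log2"] = values
    return ProbeProfile(
        case_id=case_id, quadrant=quadrant, week=week, probes=df,
        cellularity=cellularity,
    )


def write_probe_table(profile: ProbeProfile, path: str | Path) -> Path:
    path = Path(path)
    df = profile.probes.rename(columns={"pos": "pos_bp", "log2": "log2_ratio"})
    df = df[PROBE_COLUMNS].copy()
    df["log2_ratio"] = [f"{v:.6f}" for v in df["log2_ratio"]]
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# SEG / BED / Newick
# ---------------------------------------------------------------------------

def write_seg(
    segments: list[Segment], sample_id: str, path: str | Path
) -> Path:
    """SEG format: ID chrom loc.start loc.end num.mark seg.mean."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
        for s in segments:
            fh.write(
                f"{sample_id}\t{s.chrom}\t{s.start_bp}\t{s.end_bp}"
                f"\t{s.n_probes}\t{s.mean_log2:.6f}\n"
            )
    return path


def write_bed(
    called: list[CalledSegment] | list[AberrationEvent],
    path: str | Path,
    genome: GenomeModel | None = None,
) -> Path:
    """BED (0-based half-open) with the call/kind in the name field."""
    path = Path(path)
    with open(path, "w") as fh:
        for item in called:
            if isinstance(item, CalledSegment):
                fh.write(
                    f"{item.chrom}\t{item.start_bp}\t{item.end_bp}"
                    f"\t{item.call.name}\t{item.mean_log2:.4f}\n"
                )
            else:
                start = item.start_bp
                end = item.end_bp
                if start is None or end is None:
                    start = int(round(item.start.mb * 1e6))
                    end = int(round(item.end.mb * 1e6))
                fh.write(
                    f"{item.chrom}\t{start}\t{end}\t{item.kind.name}\t0\n"
                )
    return path


def write_status_csv(
    statuses: list[ProfileStatus], path: str | Path
) -> Path:
    """Profile-status table in the clinical T/F dialect: one row per
    case/week, quadrants as columns, '-' for missing samples."""
    path = Path(path)
    by_case_week: dict[tuple[str, int], dict[int, ProfileStatus]] = {}
    for s in statuses:
        by_case_week.setdefault((s.case_id, s.week), {})[s.quadrant] = s
    with open(path, "w") as fh:
        fh.write("case,week,q1,q2,q3,q4\n")
        for (case, week), quads in sorted(by_case_week.items()):
            cells = [
                ("T" if quads[q].abnormal else "F") if q in quads else "-"
                for q in (1, 2, 3, 4)
            ]
            fh.write(f"{case},{week}," + ",".join(cells) + "\n")
    return path


def write_early_events_csv(report, path: str | Path) -> Path:
    """Early-event report: one row per event with its TRUNK/BRANCH order
    class, trunk (pre-divergence) events first."""
    path = Path(path)
    rows = sorted(
        report.order_class.items(),
        key=lambda kv: (kv[1] != "TRUNK", kv[0].chrom, kv[0].start.mb),
    )
    with open(path, "w") as fh:
        fh.write("case,chrom,position,type,order\n")
        for event, order in rows:
            fh.write(
                f"{report.case_id},{event.chrom},{event.position_label},"
                f"{event.kind.value},{order}\n"
            )
    return path


def write_newick(newick: str, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(newick.rstrip("\n") + "\n")
    return path


def write_event_csv(
    matrix: EventMatrix, statuses_hom_het: dict, path: str | Path
) -> Path:
    """Report-style CSV: one row per catalogue event with status and the
    quadrants carrying it per week."""
    path = Path(path)
    rows = []
    for col, e in enumerate(matrix.events):
        weeks: dict[int, list[int]] = {}
        for s in matrix.samples:
            if matrix.presence[matrix.sample_index(s), col]:
                weeks.setdefault(s[1], []).append(s[0])
        rows.append(
            {
                "case": matrix.case_id,
                "chrom": e.chrom,
                "position": e.position_label,
                "type": e.kind.value,
                "status": statuses_hom_het.get(e, ""),
                "presence_wk0": ";".join(map(str, sorted(weeks.get(0, [])))),
                "presence_wk2": ";".join(map(str, sorted(weeks.get(2, [])))),
                "presence_wk5": ";".join(map(str, sorted(weeks.get(5, [])))),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def fixture_path(name: str) -> Path:
    return Path(str(resources.files("quadclone") / "fixtures" / name))


def load_table1_samples() -> list[ProfileStatus]:
    """Per-sample abnormal-profile flags and tumour-cell percentages.

    A missing flag means no biopsy/array for that quadrant-week; such
    samples are omitted.  '<1' percentages are carried as 0.5."""
    df = pd.read_csv(fixture_path("table1_samples.csv"), dtype=str)
    statuses = []
    for _, r in df.iterrows():
        flag = r["acgh_abnormal"]
        if not isinstance(flag, str) or flag not in ("T", "F"):
            continue
        pct = r["tumour_pct"]
        cellularity: float | None = None
        if isinstance(pct, str) and pct.strip():
            cellularity = 0.005 if pct.strip() == "<1" else float(pct) / 100.0
        statuses.append(
            ProfileStatus(
                case_id=r["case"],
                quadrant=int(r["quadrant"]),
                week=int(r["week"]),
                abnormal=(flag == "T"),
                cellularity=cellularity,
            )
        )
    return statuses


def load_table1_clinical() -> pd.DataFrame:
    return pd.read_csv(fixture_path("table1_clinical.csv"))


def _parse_quadrants(cell) -> list[int]:
    if not isinstance(cell, str) or not cell.strip():
        return []
    return [int(tok) for tok in cell.split(";")]


def load_table2_matrices(
    genome: GenomeModel | None = None,
) -> dict[str, EventMatrix]:
    """Per-case event matrices from the published aberration table.

    Samples are the case's aberrant profiles (from the sample-flag
    fixture).  Heterogeneous rows list the quadrants carrying the event
    per week; homogeneous rows are, by definition, present in every
    aberrant sample."""
    if genome is None:
        genome = GenomeModel.default()
    df = pd.read_csv(fixture_path("table2_events.csv"), dtype=str)
    statuses = load_table1_samples()
    matrices: dict[str, EventMatrix] = {}
    for case, sub in df.groupby("case", sort=False):
        aberrant = [
            s.sample_key
            for s in statuses
            if s.case_id == case and s.abnormal
        ]
        aberrant.sort(key=lambda qw: (qw[1], qw[0]))
        events: list[AberrationEvent] = []
        presence = np.zeros((len(aberrant), len(sub)), dtype=bool)
        for col, (_, r) in enumerate(sub.iterrows()):
            event = parse_position(
                r["chrom"], r["position"], KIND_BY_NAME[r["type"]], genome
            )
            events.append(event)
            if r["status"].strip().lower() == "hom":
                presence[:, col] = True
            else:
                for week, colname in ((0, "week0"), (2, "week2"), (5, "week5")):
                    for q in _parse_quadrants(r[colname]):
                        if (q, week) in aberrant:
                            presence[aberrant.index((q, week)), col] = True
        matrices[case] = EventMatrix(
            case_id=case, events=events, samples=aberrant, presence=presence
        )
    return matrices


def load_table2_hom_status() -> dict[str, dict[str, str]]:
    """Published Hom/Het status keyed by case and 'chrom position type'."""
    df = pd.read_csv(fixture_path("table2_events.csv"), dtype=str)
    out: dict[str, dict[str, str]] = {}
    for _, r in df.iterrows():
        key = f"{r['chrom']} {r['position']} {r['type']}"
        out.setdefault(r["case"], {})[key] = r["status"].strip()
    return out


def load_recruitment() -> dict[str, int]:
    return json.loads(fixture_path("recruitment.json").read_text())


def cohort_filter(recruitment: dict[str, int]) -> int:
    """Evaluable cases: recruited minus single-timepoint dropouts minus
    patients who did not receive chemo-RT."""
    recruited = int(recruitment["recruited"])
    excluded = int(recruitment["dropped_single_timepoint"]) + int(
        recruitment["no_chemo_rt"]
    )
    if min(recruited, excluded) < 0:
        raise ValueError("recruitment counts must be >= 0")
    if excluded > recruited:
        raise ValueError("exclusions exceed recruitment")
    return recruited - excluded
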