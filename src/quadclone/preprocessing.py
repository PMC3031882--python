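"""Probe-level normalisation and circular binary segmentation (CBS).

The segmenter follows Olshen et al. (2004): within each chromosome the
arc (i, j) maximising a two-sample t-like statistic between the probes
inside and outside the arc is tested by permutation; accepted splits are
applied recursively until no significant arc remains.  Adjacent segments
whose means differ by less than ``undo_sd`` robust standard deviations of
the probe residuals are re-merged, mirroring DNAcopy's "undo" pruning.

Determinism: the permutation stream for every tested sub-interval is
seeded from ``(seed, chromosome index, lo, hi)``, so results do not
depend on recursion order and decreasing ``alpha`` can only remove
splits, never add them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numba
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ProbeProfile",
    "Segment",
    "median_normalize",
    "cbs_segment",
    "max_arc_statistic",
]

_EPS = 1e-12
_BIG = np.inf


@dataclass
class ProbeProfile:
    """One sample's probe-level log2 ratios plus sample metadata.

    ``probes`` holds columns ``probe_id, chrom, pos, log2`` sorted by
    (chromosome order, position).  ``cellularity`` is the tumour-cell
    fraction of the biopsy in [0, 1], or None when not assessed.
    """

    case_id: str
    quadrant: int
    week: int
    probes: pd.DataFrame
    cellularity: float | None = None

    def __post_init__(self) -> None:
        if self.quadrant not in (1, 2, 3, 4):
            raise ValueError("quadrant must be 1-4")
        required = {"probe_id", "chrom", "pos", "log2"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"probe table lacks columns {sorted(missing)}")
        self.probes = self.probes.reset_index(drop=True)
        self.probes["chrom"] = self.probes["chrom"].astype(str)

    @property
    def sample_key(self) -> tuple[int, int]:
        return (self.quadrant, self.week)

    @property
    def name(self) -> str:
        return f"{self.case_id}_q{self.quadrant}_wk{self.week}"

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.probes.loc[self.probes["chrom"] == str(chrom), "log2"].to_numpy()

    def check_sorted(self) -> None:
        for _, sub in self.probes.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos"].to_numpy()) < 0):
                raise ValueError("probes are not sorted by position")


@dataclass(frozen=True)
class Segment:
    """A piecewise-constant copy-number segment (bp, half-open)."""

    chrom: str
    start_bp: int
    end_bp: int
    n_probes: int
    mean_log2: float

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("segment must contain at least one probe")
        if not self.start_bp < self.end_bp:
            raise ValueError("segment must have positive span")

    @property
    def span_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


def median_normalize(profile: ProbeProfile) -> ProbeProfile:
    """Shift log2 ratios so the profile median is zero.

    Stromal dilution and labelling differences move the whole profile up
    or down; the median is a robust baseline because most of the genome
    is copy-number neutral in these tumours.
    """
    values = profile.probes["log2"].to_numpy(dtype=float)
    if len(values) == 0:
        raise ValueError("cannot normalise an empty profile")
    if not np.all(np.isfinite(values)):
        raise ValueError("log2 ratios must be finite before normalisation")
    shifted = profile.probes.copy()
    shifted["log2"] = values - np.median(values)
    return replace(profile, probes=shifted)


# ---------------------------------------------------------------------------
# CBS internals
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _arc_stat2_one(x: np.ndarray) -> tuple[float, int, int]:
    """Squared max arc statistic and its (i, j) for one sequence.

    The squared pooled-variance two-sample t statistic between the probes
    inside arc [i, j) and the probes outside it, maximised over all arcs
    excluding the full sequence.  A zero pooled variance with a non-zero
    mean difference scores +inf (noiseless step).  Ties break on the
    smallest start index, then the smallest width.
    """
    n = x.shape[0]
    S = np.empty(n + 1)
    S2 = np.empty(n + 1)
    S[0] = 0.0
    S2[0] = 0.0
    for i in range(n):
        S[i + 1] = S[i] + x[i]
        S2[i + 1] = S2[i] + x[i] * x[i]
    total = S[n]
    total2 = S2[n]
    df = n - 2 if n > 2 else 1
    best = 0.0
    best_i = 0
    best_w = n
    for w in range(1, n):
        n_in = w
        n_out = n - w
        inv = 1.0 / n_in + 1.0 / n_out
        for i in range(0, n - w + 1):
            sum_in = S[i + w] - S[i]
            sq_in = S2[i + w] - S2[i]
            ss_in = sq_in - sum_in * sum_in / n_in
            sum_out = total - sum_in
            ss_out = (total2 - sq_in) - sum_out * sum_out / n_out
            var = (ss_in + ss_out) / df * inv
            diff = sum_in / n_in - sum_out / n_out
            if var > _EPS:
                t2 = diff * diff / var
            elif diff * diff < _EPS:
                t2 = 0.0
            else:
                t2 = np.inf
            # complementary arcs have analytically equal statistics but
            # may differ in the last ulp: treat near-equal as ties and
            # break by smallest start, then smallest width
            if t2 > best * (1.0 + 1e-10) and t2 > best:
                best = t2
                best_i = i
                best_w = w
            elif t2 >= best * (1.0 - 1e-10) and (
                i < best_i or (i == best_i and w < best_w)
            ):
                best = max(best, t2)
                best_i = i
                best_w = w
    return best, best_i, best_i + best_w


@numba.njit(cache=False)
def _arc_stats2_batch(x: np.ndarray) -> np.ndarray:
    """Row-wise squared maximum arc statistic for a batch of sequences."""
    b = x.shape[0]
    out = np.empty(b)
    for r in range(b):
        best, _, _ = _arc_stat2_one(x[r])
        out[r] = best
    return out


def max_arc_statistic(x: np.ndarray) -> tuple[float, int, int]:
    """Best arc (t statistic, i, j) for one sequence; deterministic
    tie-break by smallest start index then smallest width."""
    x = np.ascontiguousarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return 0.0, 0, n
    t2, i, j = _arc_stat2_one(x)
    return float(np.sqrt(t2)), int(i), int(j)


def _perm_decision(
    x: np.ndarray,
    observed: float,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[bool, float]:
    """Permutation test of the max arc statistic.

    Returns (significant, p).  Stops early once enough permutations have
    exceeded the observed statistic that the final p-value over the full
    ``n_perm`` draws is guaranteed to be >= alpha; the accept/reject
    decision is therefore identical to running all permutations.
    """
    if observed <= 0:
        return False, 1.0
    if not np.isfinite(observed):
        return True, 0.0
    exceed = 0
    done = 0
    obs2 = observed * observed
    block = 32  # most null intervals are rejected within the first block
    while done < n_perm:
        b = min(block, n_perm - done)
        block = min(block * 4, 512)
        perms = rng.permuted(np.broadcast_to(x, (b, len(x))).copy(), axis=1)
        stats2 = _arc_stats2_batch(perms)
        exceed += int(np.sum(stats2 >= obs2))
        done += b
        if (exceed + 1) / (n_perm + 1) >= alpha:
            return False, (exceed + 1) / (done + 1)
    p = (exceed + 1) / (n_perm + 1)
    return p < alpha, p


def _segment_indices(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    seed_key: tuple[int, int],
    min_width: int = 2,
) -> list[int]:
    """Recursive CBS change-point search; returns sorted breakpoints."""
    n = len(x)
    breaks: set[int] = set()
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        m = hi - lo
        if m < 2 * min_width:
            continue
        stat, i, j = max_arc_statistic(x[lo:hi])
        if stat <= 0:
            continue
        rng = np.random.default_rng(
            [seed_key[0] & 0x7FFFFFFF, seed_key[1], lo, hi]
        )
        significant, _ = _perm_decision(x[lo:hi], stat, alpha, n_perm, rng)
        if not significant:
            continue
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            continue
        breaks.update(cuts)
        edges = [lo, *cuts, hi]
        for a, b in zip(edges[:-1], edges[1:]):
            stack.append((a, b))
    return sorted(breaks)


def _undo_merge(
    values: np.ndarray, edges: list[int], threshold: float
) -> list[int]:
    """Iteratively remove the breakpoint with the smallest mean jump
    while that jump is below ``threshold``."""
    edges = list(edges)
    while len(edges) > 2:
        means = [
            float(np.mean(values[a:b])) for a, b in zip(edges[:-1], edges[1:])
        ]
        jumps = [abs(means[k + 1] - means[k]) for k in range(len(means) - 1)]
        k = int(np.argmin(jumps))
        if jumps[k] < threshold + _EPS:
            del edges[k + 1]
        else:
            break
    return edges


def cbs_segment(
    profile: ProbeProfile,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    undo_sd: float = 1.0,
    min_width: int = 2,
) -> list[Segment]:
    """Segment a normalised profile into constant copy-number segments.

    Parameters
    ----------
    alpha : permutation significance level for accepting a split.
    n_perm : permutations per tested interval (tests often use ~1000;
        lower values trade a coarser p-value grid for speed).
    seed : global seed; per-chromosome, per-interval streams are derived
        from it so output is reproducible and order-independent.
    undo_sd : adjacent segments whose means differ by less than
        ``undo_sd`` x (scaled MAD of probe residuals) are re-merged.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    profile.check_sorted()

    chrom_order: list[str] = list(dict.fromkeys(profile.probes["chrom"]))
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in chrom_order:
        sub = profile.probes[profile.probes["chrom"] == chrom]
        per_chrom[chrom] = (
            sub["pos"].to_numpy(dtype=np.int64),
            sub["log2"].to_numpy(dtype=float),
        )

    edges_by_chrom: dict[str, list[int]] = {}
    residuals: list[np.ndarray] = []
    for ci, chrom in enumerate(chrom_order):
        pos, vals = per_chrom[chrom]
        n = len(vals)
        if n < 4:
            edges = [0, n]
        else:
            breaks = _segment_indices(vals, alpha, n_perm, (seed, ci), min_width)
            edges = [0, *breaks, n]
        edges_by_chrom[chrom] = edges
        res = vals.copy()
        for a, b in zip(edges[:-1], edges[1:]):
            res[a:b] -= np.mean(vals[a:b])
        residuals.append(res)

    mad = float(
        sps.median_abs_deviation(np.concatenate(residuals), scale="normal")
    )
    threshold = undo_sd * mad

    segments: list[Segment] = []
    for chrom in chrom_order:
        pos, vals = per_chrom[chrom]
        edges = _undo_merge(vals, edges_by_chrom[chrom], threshold)
        n = len(vals)
        for a, b in zip(edges[:-1], edges[1:]):
            # DNAcopy convention: a segment spans its first to last probe.
            # Segments partition the probe sequence (contiguous in probe
            # index), not the base-pair line between probes.
            start = int(pos[a])
            end = int(pos[b - 1]) + 1
            segments.append(
                Segment(
                    chrom=chrom,
                    start_bp=start,
                    end_bp=end,
                    n_probes=b - a,
                    mean_log2=float(np.mean(vals[a:b])),
                )
            )
    return segments
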