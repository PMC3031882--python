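"""Reference genome model: chromosome sizes, centromeres and the probe grid.

Coordinates follow the hg18 assembly era, matching the one-decimal-Mb
coordinate dialect used in clinical aCGH reports of that generation
(e.g. "153.8-q tel").  All internal coordinates are 0-based, half-open
base pairs; megabase values appear only at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MB = 1_000_000

# hg18 chromosome lengths (bp) and approximate centromere midpoints (Mb).
# The X chromosome is carried at a diploid baseline: the intended cohort
# (cervical carcinoma) is all female.
_HG18: list[tuple[str, int, float]] = [
    ("1", 247_249_719, 124.2),
    ("2", 242_951_149, 93.2),
    ("3", 199_501_827, 91.6),
    ("4", 191_273_063, 50.9),
    ("5", 180_857_866, 47.7),
    ("6", 170_899_992, 60.5),
    ("7", 158_821_424, 59.1),
    ("8", 146_274_826, 45.2),
    ("9", 140_273_252, 48.8),
    ("10", 135_374_737, 40.3),
    ("11", 134_452_384, 52.9),
    ("12", 132_349_534, 35.4),
    ("13", 114_142_980, 16.0),
    ("14", 106_368_585, 15.6),
    ("15", 100_338_915, 15.8),
    ("16", 88_827_254, 38.2),
    ("17", 78_774_742, 22.2),
    ("18", 76_117_153, 16.1),
    ("19", 63_811_651, 28.5),
    ("20", 62_435_964, 27.1),
    ("21", 46_944_323, 12.3),
    ("22", 49_691_432, 14.7),
    ("X", 154_913_754, 59.5),
]


@dataclass(frozen=True)
class Chromosome:
    """One chromosome with its centromere splitting p and q arms."""

    name: str
    length_bp: int
    centromere_bp: int

    def __post_init__(self) -> None:
        if not 0 < self.centromere_bp < self.length_bp:
            raise ValueError(
                f"centromere of chromosome {self.name} must lie strictly "
                f"inside (0, {self.length_bp})"
            )

    @property
    def length_mb(self) -> float:
        return self.length_bp / MB

    @property
    def centromere_mb(self) -> float:
        return self.centromere_bp / MB

    def arms(self) -> list[tuple[str, int, int]]:
        """(arm name, start_bp, end_bp) for the p and q arms."""
        return [
            ("p", 0, self.centromere_bp),
            ("q", self.centromere_bp, self.length_bp),
        ]


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome table plus an ordered probe grid per chromosome.

    Probe positions are strictly increasing within each chromosome.  The
    default grid spreads a configurable total probe count across
    chromosomes proportionally to their length, emulating the even
    genome-wide tiling of catalogue oligo-aCGH designs (the real platform
    carries ~180k probes; ~4000 keeps desk-scale runs fast while leaving
    plenty of probes per chromosome arm).
    """

    chromosomes: tuple[Chromosome, ...]
    probes: dict[str, np.ndarray] = field(compare=False)

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            pos = self.probes.get(chrom.name)
            if pos is None or len(pos) == 0:
                raise ValueError(f"chromosome {chrom.name} has no probes")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"probe positions on chromosome {chrom.name} must be "
                    "strictly increasing"
                )
            if pos[0] < 0 or pos[-1] >= chrom.length_bp:
                raise ValueError(
                    f"probes on chromosome {chrom.name} fall outside the "
                    "chromosome"
                )

    @classmethod
    def default(cls, n_probes: int = 4000) -> "GenomeModel":
        """hg18-era genome with ``n_probes`` evenly tiled probes."""
        chroms = tuple(
            Chromosome(name, length, int(round(cen * MB)))
            for name, length, cen in _HG18
        )
        total = sum(c.length_bp for c in chroms)
        probes: dict[str, np.ndarray] = {}
        for c in chroms:
            k = max(4, int(round(n_probes * c.length_bp / total)))
            # probes at the midpoints of k equal bins; integral positions
            step = c.length_bp / k
            probes[c.name] = (step * (np.arange(k) + 0.5)).astype(np.int64)
        return cls(chromosomes=chroms, probes=probes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == str(name):
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom_index(self, name: str) -> int:
        return self.chrom_names.index(str(name))

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p in self.probes.values())

    def probe_spacing_bp(self, chrom: str) -> float:
        pos = self.probes[str(chrom)]
        if len(pos) < 2:
            return float(self.chromosome(chrom).length_bp)
        return float(np.median(np.diff(pos)))
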