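"""Per-CpG methylation tracks and the three-state methylation categorization.

A methylome here is a set of CpG sites (position of the C on the forward
strand, strand-merged) each carrying a methylation level in [0, 1] — the
output of a single-CpG predictor or of WGBS.  Region summaries are plain
arithmetic means over the CpGs falling in the region, and methylation status
follows the standard three-state scheme: unmethylated (< 0.3), intermediately
methylated ([0.3, 0.7]), methylated (> 0.7).  The 0.3 and 0.7 boundaries are
intermediate because the defining inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "UNMETHYLATED",
    "INTERMEDIATE",
    "METHYLATED",
    "CpGSite",
    "RegionMethylation",
    "MethylomeTrack",
    "categorize",
    "region_mean",
]

UNMETHYLATED = 0
INTERMEDIATE = 1
METHYLATED = 2


class CpGSite(NamedTuple):
    chrom: str
    pos: int
    level: float


@dataclass(frozen=True)
class RegionMethylation:
    """Mean methylation over a region; ``mean_level`` is None when the region
    contains no CpG."""

    interval: GenomicInterval
    mean_level: float | None
    n_cpg: int

    def __post_init__(self) -> None:
        if (self.n_cpg > 0) != (self.mean_level is not None):
            raise ValueError("mean_level must be defined iff n_cpg > 0")


def categorize(mean_level: float) -> int:
    """Three-state methylation status of a defined mean level.

    < 0.3 -> 0 (unmethylated); > 0.7 -> 2 (methylated); otherwise 1.
    """
    if not (0.0 <= mean_level <= 1.0):
        raise ValueError(f"methylation level {mean_level} outside [0, 1]")
    if mean_level < 0.3:
        return UNMETHYLATED
    if mean_level > 0.7:
        return METHYLATED
    return INTERMEDIATE


class MethylomeTrack:
    """CpG methylation levels for one species x tissue.

    Positions are unique per contig and stored sorted, so region queries are
    two binary searches.
    """

    def __init__(self, species: str = "", tissue: str = "") -> None:
        self.species = species
        self.tissue = tissue
        self._pos: dict[str, np.ndarray] = {}
        self._lev: dict[str, np.ndarray] = {}

    @classmethod
    def from_sites(cls, sites, species: str = "", tissue: str = "") -> "MethylomeTrack":
        track = cls(species, tissue)
        by_chrom: dict[str, list[tuple[int, float]]] = {}
        for chrom, pos, level in sites:
            by_chrom.setdefault(chrom, []).append((pos, level))
        for chrom, pl in by_chrom.items():
            pl.sort()
            pos = np.array([p for p, _ in pl], dtype=np.int64)
            lev = np.array([l for _, l in pl], dtype=np.float64)
            track._set_contig(chrom, pos, lev)
        return track

    @classmethod
    def from_bedgraph(cls, path, species: str = "", tissue: str = "") -> "MethylomeTrack":
        """Read a bedGraph of CpG levels.

        Both 1-bp and 2-bp CpG features occur in the wild; the start
        coordinate is taken as the CpG position either way.
        """
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "level"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "level": np.float64},
        )
        df = df[~df["chrom"].str.startswith(("track", "browser"))]
        track = cls(species, tissue)
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            track._set_contig(chrom, sub["start"].to_numpy(), sub["level"].to_numpy())
        return track

    def _set_contig(self, chrom: str, pos: np.ndarray, lev: np.ndarray) -> None:
        if len(np.unique(pos)) != len(pos):
            raise ValueError(f"duplicate CpG positions on {chrom}")
        if ((lev < 0) | (lev > 1)).any():
            raise ValueError(f"methylation levels outside [0, 1] on {chrom}")
        self._pos[chrom] = np.asarray(pos, dtype=np.int64)
        self._lev[chrom] = np.asarray(lev, dtype=np.float64)

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self._pos.values())

    def sites(self) -> Iterator[CpGSite]:
        for chrom in sorted(self._pos):
            for p, l in zip(self._pos[chrom], self._lev[chrom]):
                yield CpGSite(chrom, int(p), float(l))

    def levels_in(self, iv: GenomicInterval) -> np.ndarray:
        pos = self._pos.get(iv.chrom)
        if pos is None:
            return np.empty(0)
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        return self._lev[iv.chrom][lo:hi]

    def region_mean(self, iv: GenomicInterval) -> RegionMethylation:
        lev = self.levels_in(iv)
        if len(lev) == 0:
            return RegionMethylation(iv, None, 0)
        return RegionMethylation(iv, float(lev.mean()), int(len(lev)))

    def to_bedgraph(self, path, width: int = 2) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._pos):
                for p, l in zip(self._pos[chrom], self._lev[chrom]):
                    fh.write(f"{chrom}\t{p}\t{p + width}\t{l:.3f}\n")


def region_mean(track: MethylomeTrack, interval: GenomicInterval) -> RegionMethylation:
    """Mean methylation of CpGs with positions in [start, end)."""
    return track.region_mean(interval)
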