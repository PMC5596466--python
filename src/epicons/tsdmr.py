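"""Tissue-specific hypomethylated DMR calling on fixed-size windows.

A tsDMR is a 500-bp window hypomethylated in exactly one of three tissues and
methylated (or at least clearly more methylated) in the other two.  Two
criteria define a call from per-tissue window mean methylation:

  1. hypo-vs-nonhypo: target < 0.3 and both other tissues >= 0.3;
  2. intermediate-vs-hyper: 0.3 <= target <= 0.7 and both others > 0.7.

An optional upstream differential-methylation q-value (< 1e-5 by default)
gates the call when supplied; when absent the level criteria alone decide.
Hypermethylated tsDMRs are deliberately not called.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .methylome import MethylomeTrack

__all__ = [
    "WindowScores",
    "TsDMR",
    "call_window",
    "call_all",
    "scores_from_tracks",
    "load_window_scores",
    "calls_to_bed",
]

DEFAULT_Q_THRESHOLD = 1e-5


@dataclass(frozen=True)
class WindowScores:
    """Per-tissue mean methylation for one genomic window, plus an optional
    per-window differential-methylation q-value."""

    interval: GenomicInterval
    levels: Mapping[str, float]
    qvalue: float | None = None

    def __post_init__(self) -> None:
        for tissue, level in self.levels.items():
            if not (0.0 <= level <= 1.0):
                raise ValueError(f"level for {tissue} outside [0, 1]: {level}")


@dataclass(frozen=True)
class TsDMR:
    interval: GenomicInterval
    target_tissue: str
    species: str = ""
    criterion: int = 1  # 1 = hypo-vs-nonhypo, 2 = intermediate-vs-hyper

    def key(self) -> tuple:
        return (self.interval.chrom, self.interval.start, self.interval.end)


def call_window(
    ws: WindowScores,
    target: str,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    species: str = "",
) -> TsDMR | None:
    """Apply the two-criterion tsDMR rule to one window for one target tissue.

    Returns a :class:`TsDMR` or None.  Requires exactly three tissues — the
    rule is written for exactly two "other" tissues.
    """
    if len(ws.levels) != 3:
        raise ValueError(f"expected exactly 3 tissues, got {len(ws.levels)}")
    if target not in ws.levels:
        raise ValueError(f"target tissue {target!r} not among {sorted(ws.levels)}")
    if ws.qvalue is not None and not (ws.qvalue < q_threshold):
        return None
    lt = ws.levels[target]
    others = [lvl for tissue, lvl in ws.levels.items() if tissue != target]
    if lt < 0.3 and all(o >= 0.3 for o in others):
        return TsDMR(ws.interval, target, species, criterion=1)
    if 0.3 <= lt <= 0.7 and all(o > 0.7 for o in others):
        return TsDMR(ws.interval, target, species, criterion=2)
    return None


def call_all(
    windows: Iterable[WindowScores],
    tissues: Sequence[str],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    species: str = "",
) -> dict[str, list[TsDMR]]:
    """Call tsDMRs for every tissue over a window collection.

    The criteria make per-tissue output sets disjoint (hypomethylation in one
    tissue excludes a call for any other); this is asserted on every run.
    """
    if len(tissues) != 3:
        raise ValueError("exactly 3 tissues required")
    out: dict[str, list[TsDMR]] = {t: [] for t in tissues}
    for ws in windows:
        hit = None
        for tissue in tissues:
            dmr = call_window(ws, tissue, q_threshold=q_threshold, species=species)
            if dmr is not None:
                assert hit is None, "tsDMR criteria produced two target tissues"
                out[tissue].append(dmr)
                hit = tissue
    return out


def scores_from_tracks(
    tracks: Mapping[str, MethylomeTrack],
    tiles: IntervalSet,
    qvalues: Mapping[tuple[str, int], float] | None = None,
    min_cpg: int = 1,
) -> list[WindowScores]:
    """Window mean methylation per tissue from per-CpG tracks.

    Windows without a defined mean in every tissue (fewer than ``min_cpg``
    CpGs in some track) are dropped — the rule needs all three tissues.
    ``qvalues`` maps (chrom, window start) to an upstream q-value.
    """
    out: list[WindowScores] = []
    for iv in tiles:
        levels: dict[str, float] = {}
        ok = True
        for tissue, track in tracks.items():
            rm = track.region_mean(iv)
            if rm.n_cpg < min_cpg or rm.mean_level is None:
                ok = False
                break
            levels[tissue] = rm.mean_level
        if not ok:
            continue
        q = qvalues.get((iv.chrom, iv.start)) if qvalues is not None else None
        out.append(WindowScores(iv, levels, q))
    return out


def load_window_scores(path, tissues: Sequence[str]) -> list[WindowScores]:
    """Read a window-score table: chrom, start, end, one level column per
    tissue, then an optional qvalue column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["chrom", "start", "end", *tissues]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"window-score table missing columns: {missing}")
    has_q = "qvalue" in df.columns
    out = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(getattr(row, "chrom")), int(getattr(row, "start")),
                             int(getattr(row, "end")))
        levels = {t: float(getattr(row, t)) for t in tissues}
        q = float(getattr(row, "qvalue")) if has_q else None
        out.append(WindowScores(iv, levels, q))
    return out


def calls_to_bed(calls: Mapping[str, list[TsDMR]]) -> IntervalSet:
    """Flatten per-tissue calls into a BED6+-shaped interval set with the
    target tissue in the name column and the criterion as an extra column."""
    out = IntervalSet(name="tsdmrs")
    for tissue in calls:
        for i, dmr in enumerate(calls[tissue]):
            out.append(dmr.interval,
                       (f"{tissue}_{i}", "0", ".", tissue, str(dmr.criterion)))
    return out
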