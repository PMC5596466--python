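"""Genetic-conservation labelling and the conservation-score binned EC curve.

A region is genetically conserved when at least 20% of its bases overlap
phastCons-style conserved elements.  The score-binned curve splits each 500-bp
tsDMR into 50-bp subwindows, lifts each to the comparison species, averages a
per-base conservation score (phyloP-style) over the mapped bases, sorts the
subwindows by that mean, partitions them into equal-sized bins of increasing
score, and reports the fraction of epigenetically conserved members per bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .conservation import EC, classify_ec
from .intervals import GenomicInterval, IntervalSet, ScoreTrack, overlap_bases
from .methylome import MethylomeTrack, categorize
from .orthology import liftover_interval
from .tsdmr import TsDMR

__all__ = ["GeneticConservationCall", "genetic_call", "phylop_ec_curve"]


@dataclass(frozen=True)
class GeneticConservationCall:
    region: GenomicInterval
    overlap_fraction: float
    conserved: bool


def genetic_call(
    region: GenomicInterval,
    elements: IntervalSet,
    min_frac: float = 0.2,
) -> GeneticConservationCall:
    """Conserved iff >= ``min_frac`` of the region overlaps the element set
    (boundary inclusive)."""
    frac = overlap_bases(region, elements) / len(region)
    return GeneticConservationCall(region, frac, frac >= min_frac)


def _subwindow_ec(
    target: GenomicInterval,
    tracks: Mapping[str, MethylomeTrack],
    target_tissue: str,
) -> bool | None:
    """EC/ENC of one mapped subwindow; None when some tissue lacks CpGs."""
    statuses: dict[str, int] = {}
    for tissue, track in tracks.items():
        rm = track.region_mean(target)
        if rm.n_cpg == 0:
            return None
        statuses[tissue] = categorize(rm.mean_level)
    return classify_ec(statuses, target_tissue) == EC


def phylop_ec_curve(
    tsdmrs: Sequence[TsDMR],
    score_track: ScoreTrack,
    chains,
    methylomes: Mapping[str, MethylomeTrack],
    n_bins: int = 100,
    subwindow: int = 50,
    min_cover: float = 0.5,
    max_span: int = 1000,
    level: str = "subwindow",
) -> pd.DataFrame:
    """Epigenetic-conservation fraction across conservation-score bins.

    ``level`` selects whether EC is evaluated per 50-bp subwindow ortholog
    ("subwindow", default) or inherited from the parent 500-bp ortholog
    ("parent").  Subwindows that fail liftover, have no score data, or whose
    ortholog lacks CpGs in some tissue are excluded.  Bins are equal-sized;
    when the count is not divisible by ``n_bins`` the remainder is assigned
    one-per-bin starting from the lowest-score bins.  Ties in mean score break
    by genomic order so the binning is deterministic.
    """
    if level not in ("subwindow", "parent"):
        raise ValueError("level must be 'subwindow' or 'parent'")
    entries: list[tuple[float, tuple, bool]] = []
    for dmr in tsdmrs:
        iv = dmr.interval
        if len(iv) % subwindow:
            raise ValueError(
                f"tsDMR length {len(iv)} not divisible by subwindow {subwindow}"
            )
        parent_ec: bool | None = None
        if level == "parent":
            parent_lift = liftover_interval(chains, iv, min_cover=min_cover,
                                            max_span=max_span)
            if not parent_lift.mapped:
                continue
            parent_ec = _subwindow_ec(parent_lift.target, methylomes,
                                      dmr.target_tissue)
            if parent_ec is None:
                continue
        for start in range(iv.start, iv.end, subwindow):
            sub = GenomicInterval(iv.chrom, start, start + subwindow)
            lift = liftover_interval(chains, sub, min_cover=min_cover,
                                     max_span=max_span)
            if not lift.mapped:
                continue
            mean_score = score_track.mean(lift.target)
            if math.isnan(mean_score):
                continue
            if level == "parent":
                is_ec = parent_ec
            else:
                is_ec = _subwindow_ec(lift.target, methylomes, dmr.target_tissue)
                if is_ec is None:
                    continue
            entries.append((mean_score, (sub.chrom, sub.start), bool(is_ec)))
    n = len(entries)
    if n < n_bins:
        raise ValueError(
            f"only {n} mapped subwindows for {n_bins} bins; use a smaller n_bins"
        )
    entries.sort(key=lambda e: (e[0], e[1]))
    base, rem = divmod(n, n_bins)
    rows = []
    pos = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        chunk = entries[pos:pos + size]
        pos += size
        scores = [e[0] for e in chunk]
        rows.append({
            "bin": b + 1,
            "n": size,
            "score_min": min(scores),
            "score_max": max(scores),
            "ec_fraction": sum(e[2] for e in chunk) / size,
        })
    assert pos == n
    return pd.DataFrame(rows)
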