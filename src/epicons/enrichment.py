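"""Feature annotation, matched background sampling, and enrichment statistics.

Windows are annotated with a single genomic-feature label: a feature qualifies
only when its (flattened) intervals cover more than 50% of the window, and
when several qualify a fixed precedence order decides (promoter > CGI > 5'UTR
> exon > 3'UTR > TE > intron > intergenic).  Intergenic is the complement of
transcript spans; a window that is mostly genic but has no single qualifying
sub-feature is labelled 'other'.

Matched backgrounds are stratified uniform samples without replacement that
reproduce a target set's feature composition exactly.  Chi-square tests are
Pearson tests without continuity correction; multiple testing uses
Benjamini-Hochberg throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .intervals import (
    GeneRecord,
    GenomicInterval,
    IntervalSet,
    ScoreTrack,
    overlap_bases,
)

__all__ = [
    "FEATURE_PRECEDENCE",
    "AnnotationBundle",
    "MatchedBackground",
    "HistonePeak",
    "assign_feature",
    "sample_matched",
    "nearest_tss",
    "distance_enrichment",
    "summit_overlap",
    "signal_profile",
    "bh_fdr",
    "chi2_2x2",
    "parse_peaks",
    "DEFAULT_DISTANCE_EDGES",
]

FEATURE_PRECEDENCE = (
    "promoter", "CGI", "5utr", "exon", "3utr", "TE", "intron",
)

# distance-to-TSS bin edges in bp: [0,1), [1,2), [2,5), [5,10), [10,50),
# [50,100), [100,inf) kb
DEFAULT_DISTANCE_EDGES = (0, 1_000, 2_000, 5_000, 10_000, 50_000, 100_000, np.inf)

PROMOTER_UP = 2_000
PROMOTER_DOWN = 500


class AnnotationBundle:
    """Gene table plus CGI and repeat interval sets, with per-label flattened
    interval sets derived lazily."""

    def __init__(
        self,
        genes: Sequence[GeneRecord],
        cgi: IntervalSet | None = None,
        repeats: IntervalSet | None = None,
    ) -> None:
        self.genes = list(genes)
        self.cgi = cgi if cgi is not None else IntervalSet()
        self.repeats = repeats if repeats is not None else IntervalSet()
        self._labels: dict[str, IntervalSet] | None = None

    def label_sets(self) -> Mapping[str, IntervalSet]:
        if self._labels is not None:
            return self._labels
        promoters = IntervalSet(name="promoter")
        exons = IntervalSet(name="exon")
        introns = IntervalSet(name="intron")
        utr5 = IntervalSet(name="5utr")
        utr3 = IntervalSet(name="3utr")
        spans = IntervalSet(name="gene_span")
        for g in self.genes:
            spans.append(g.span)
            if g.strand == "+":
                p_lo, p_hi = g.tss - PROMOTER_UP, g.tss + PROMOTER_DOWN
            else:
                p_lo, p_hi = g.tss - PROMOTER_DOWN, g.tss + PROMOTER_UP
            p_lo = max(0, p_lo)
            if p_lo < p_hi:
                promoters.append(GenomicInterval(g.chrom, p_lo, p_hi))
            exon_ivs = [
                GenomicInterval(g.chrom, s, e)
                for s, e in zip(g.exon_starts, g.exon_ends)
            ]
            for iv in exon_ivs:
                exons.append(iv)
            # introns: gene body minus exons
            if exon_ivs:
                prev = g.tx_start
                for iv in sorted(exon_ivs, key=lambda v: v.start):
                    if prev < iv.start:
                        introns.append(GenomicInterval(g.chrom, prev, iv.start))
                    prev = max(prev, iv.end)
                if prev < g.tx_end:
                    introns.append(GenomicInterval(g.chrom, prev, g.tx_end))
            else:
                introns.append(g.span)
            if g.cds_start is not None and g.cds_end is not None \
                    and g.tx_start <= g.cds_start < g.cds_end <= g.tx_end:
                left = (g.tx_start, g.cds_start)
                right = (g.cds_end, g.tx_end)
                five, three = (left, right) if g.strand == "+" else (right, left)
                if five[0] < five[1]:
                    utr5.append(GenomicInterval(g.chrom, *five))
                if three[0] < three[1]:
                    utr3.append(GenomicInterval(g.chrom, *three))
        self._labels = {
            "promoter": promoters.flatten(),
            "CGI": self.cgi.flatten() if len(self.cgi) else IntervalSet(),
            "5utr": utr5.flatten() if len(utr5) else IntervalSet(),
            "exon": exons.flatten() if len(exons) else IntervalSet(),
            "3utr": utr3.flatten() if len(utr3) else IntervalSet(),
            "TE": self.repeats.flatten() if len(self.repeats) else IntervalSet(),
            "intron": introns.flatten() if len(introns) else IntervalSet(),
            "gene_span": spans.flatten() if len(spans) else IntervalSet(),
        }
        return self._labels


def assign_feature(
    window: GenomicInterval,
    bundle: AnnotationBundle,
    precedence: Sequence[str] = FEATURE_PRECEDENCE,
) -> str:
    """Single feature label of a window under the >50% coverage rule."""
    labels = bundle.label_sets()
    half = 0.5 * len(window)
    for label in precedence:
        iset = labels.get(label)
        if iset is not None and len(iset) and overlap_bases(window, iset) > half:
            return label
    genic = overlap_bases(window, labels["gene_span"]) if len(labels["gene_span"]) else 0
    if len(window) - genic > half:
        return "intergenic"
    return "other"


@dataclass(frozen=True)
class MatchedBackground:
    windows: IntervalSet
    feature_composition: dict
    seed: int
    labels: tuple = ()


def sample_matched(
    targets: Sequence[tuple[GenomicInterval, str]],
    universe: Sequence[tuple[GenomicInterval, str]],
    seed: int,
    replace: bool = False,
) -> MatchedBackground:
    """Feature-composition-matched background sample.

    Per label, draws exactly as many universe windows as the target set has,
    uniformly without replacement (unless ``replace``).  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    want: dict[str, int] = {}
    for _, label in targets:
        want[label] = want.get(label, 0) + 1
    pool: dict[str, list[GenomicInterval]] = {}
    for iv, label in universe:
        pool.setdefault(label, []).append(iv)
    chosen: list[GenomicInterval] = []
    chosen_labels: list[str] = []
    for label in sorted(want):
        n = want[label]
        avail = pool.get(label, [])
        if len(avail) < n and not replace:
            raise ValueError(
                f"stratum {label!r}: universe has {len(avail)} windows, "
                f"need {n} (pass replace=True to sample with replacement)"
            )
        idx = rng.choice(len(avail), size=n, replace=replace)
        chosen.extend(avail[i] for i in idx)
        chosen_labels.extend([label] * n)
    return MatchedBackground(
        IntervalSet(chosen, name="matched_background"),
        dict(want), seed, tuple(chosen_labels),
    )


def nearest_tss(region: GenomicInterval, genes: Sequence[GeneRecord]) -> int | None:
    """Distance from the region start to the closest TSS on the same contig,
    irrespective of strand (TSS itself is strand-aware).  None when the contig
    has no gene."""
    tss = [g.tss for g in genes if g.chrom == region.chrom]
    if not tss:
        return None
    return int(min(abs(t - region.start) for t in tss))


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns (statistic, p).  Degenerate tables (a zero margin) give (nan, nan).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    stat, p, _, _ = chi2_contingency(t, correction=False)
    return float(stat), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def distance_enrichment(
    target_distances: Sequence[float],
    background_distances: Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_DISTANCE_EDGES,
) -> pd.DataFrame:
    """Per-distance-bin fold enrichment of targets over background.

    Fold is (targets in bin / n targets) / (background in bin / n background);
    each bin gets a Pearson chi-square on the in-bin vs out-of-bin 2x2 and BH
    correction runs across the testable bins.  Bins empty in both sets are
    reported with NaN fold/p and excluded from correction.
    """
    t = np.asarray([d for d in target_distances if d is not None], dtype=float)
    b = np.asarray([d for d in background_distances if d is not None], dtype=float)
    if t.size == 0 or b.size == 0:
        raise ValueError("both target and background distance sets must be non-empty")
    edges = np.asarray(bin_edges, dtype=float)
    t_counts, _ = np.histogram(t, bins=edges)
    b_counts, _ = np.histogram(b, bins=edges)
    rows = []
    for i in range(len(edges) - 1):
        ti, bi = int(t_counts[i]), int(b_counts[i])
        if ti == 0 and bi == 0:
            fold, p = float("nan"), float("nan")
        else:
            bg_rate = bi / b.size
            fold = (ti / t.size) / bg_rate if bg_rate > 0 else float("nan")
            _, p = chi2_2x2([[ti, t.size - ti], [bi, b.size - bi]])
        rows.append({
            "bin_lo": edges[i], "bin_hi": edges[i + 1],
            "observed": ti, "background": bi,
            "fold": fold, "chi2_p": p,
        })
    df = pd.DataFrame(rows)
    testable = df["chi2_p"].notna()
    q = np.full(len(df), np.nan)
    if testable.any():
        q[testable.to_numpy()] = bh_fdr(df.loc[testable, "chi2_p"].to_numpy())
    df["bh_q"] = q
    return df


@dataclass(frozen=True)
class HistonePeak:
    """A ChIP-seq peak with the absolute position of its summit."""

    interval: GenomicInterval
    summit: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak {self.interval}"
            )


def parse_peaks(path, summit_col: int = 9, absolute: bool = False) -> list[HistonePeak]:
    """Read a peak BED with a summit column (narrowPeak dialect by default:
    column 10 holds the summit offset from the peak start)."""
    from .intervals import parse_bed

    iset = parse_bed(path)
    peaks = []
    for iv, extra in zip(iset.intervals, iset.extras):
        cols = (iv.chrom, str(iv.start), str(iv.end), *extra)
        raw = int(cols[summit_col])
        summit = raw if absolute else iv.start + raw
        peaks.append(HistonePeak(GenomicInterval(iv.chrom, iv.start, iv.end), summit))
    return peaks


def _summit_index(peaks: Sequence[HistonePeak]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p.summit)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in by_chrom.items()}


def _count_with_summit(regions: Iterable[GenomicInterval], idx) -> int:
    n = 0
    for iv in regions:
        summits = idx.get(iv.chrom)
        if summits is None:
            continue
        lo = np.searchsorted(summits, iv.start, side="left")
        hi = np.searchsorted(summits, iv.end, side="left")
        if hi > lo:
            n += 1
    return n


def summit_overlap(
    ec_regions: Sequence[GenomicInterval],
    enc_regions: Sequence[GenomicInterval],
    peaks: Sequence[HistonePeak],
) -> dict:
    """Summit-containment overlap counts for EC vs ENC regions.

    A region overlaps a mark iff it contains a peak summit (half-open).  The
    returned dict holds the four counts and a Pearson chi-square comparing the
    two overlap rates.
    """
    idx = _summit_index(peaks)
    ec_hit = _count_with_summit(ec_regions, idx)
    enc_hit = _count_with_summit(enc_regions, idx)
    n_ec, n_enc = len(ec_regions), len(enc_regions)
    stat, p = chi2_2x2([[ec_hit, n_ec - ec_hit], [enc_hit, n_enc - enc_hit]])
    return {
        "n_ec": n_ec, "ec_overlap": ec_hit,
        "n_enc": n_enc, "enc_overlap": enc_hit,
        "chi2": stat, "p_value": p,
    }


def signal_profile(
    regions: Sequence[GenomicInterval],
    density: ScoreTrack,
    flank: int = 5_000,
    binsize: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Average signal density around region midpoints.

    Returns (offsets, means): bin left edges relative to the midpoint
    (-flank .. flank - binsize) and the across-region mean of per-bin mean
    density.  Bases without data count as 0.
    """
    if flank % binsize:
        raise ValueError("flank must be a multiple of binsize")
    n_bins = 2 * flank // binsize
    acc = np.zeros(n_bins)
    if not regions:
        raise ValueError("no regions given")
    for iv in regions:
        mid = (iv.start + iv.end) // 2
        lo = mid - flank
        vals = np.zeros(2 * flank)
        left_pad = max(0, -lo)
        win_lo = max(0, lo)
        win_hi = mid + flank
        got = density.values(GenomicInterval(iv.chrom, win_lo, win_hi), fill=0.0)
        vals[left_pad:left_pad + len(got)] = got
        acc += vals.reshape(n_bins, binsize).mean(axis=1)
    offsets = np.arange(-flank, flank, binsize)
    return offsets, acc / len(regions)
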