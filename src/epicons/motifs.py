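"""Known-motif scanning, GC-matched enrichment, and cross-species turnover.

Motifs are IUPAC consensus strings (matched exactly, Hamming distance 0 under
the IUPAC character classes, both strands) or position weight matrices scored
as log-odds against a uniform background with a default threshold of 80% of
the maximum achievable score.  'N' in a scanned sequence matches only an 'N'
consensus position.

Turnover classification compares the motif complements of an orthologous
region pair: a source hit whose lifted image overlaps a destination hit is
conserved in place; hits on both sides with no positional correspondence are a
turnover event; one-sided hits are a loss (source only) or gain (destination
only).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, fetch_sequence
from .orthology import liftover_interval

__all__ = [
    "IUPAC",
    "MotifModel",
    "MotifHit",
    "CONSERVED_IN_PLACE",
    "TURNOVER",
    "LOSS",
    "GAIN",
    "ABSENT_BOTH",
    "reverse_complement",
    "scan",
    "scan_region",
    "gc_fraction",
    "gc_matched_background",
    "enrichment_by_ec",
    "classify_turnover",
    "parse_motif_list",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CONSERVED_IN_PLACE = "CONSERVED_IN_PLACE"
TURNOVER = "TURNOVER"
LOSS = "LOSS"
GAIN = "GAIN"
ABSENT_BOTH = "ABSENT_BOTH"


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    motif: str
    score: float | None = None


class MotifModel:
    """An IUPAC consensus or a PWM with a log-odds threshold.

    PWM rows are positions, columns A/C/G/T probabilities (rows must sum
    to 1); log-odds are taken against a uniform 0.25 background with a small
    pseudocount, and ``threshold`` defaults to 0.8 x the maximum achievable
    log-odds score.
    """

    def __init__(
        self,
        name: str,
        consensus: str | None = None,
        pwm: np.ndarray | None = None,
        threshold: float | None = None,
    ) -> None:
        if (consensus is None) == (pwm is None):
            raise ValueError("provide exactly one of consensus or pwm")
        self.name = name
        self.consensus = consensus.upper() if consensus else None
        self.pwm = None
        self.threshold = threshold
        if self.consensus is not None:
            bad = [c for c in self.consensus if c not in IUPAC]
            if bad:
                raise ValueError(f"motif {name}: non-IUPAC characters {bad}")
            self.length = len(self.consensus)
        else:
            pwm = np.asarray(pwm, dtype=float)
            if pwm.ndim != 2 or pwm.shape[1] != 4:
                raise ValueError("PWM must have shape (length, 4)")
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("PWM rows must sum to 1")
            self.pwm = pwm
            self.length = pwm.shape[0]
            lo = np.log2((pwm + 1e-4) / 0.25)
            self._logodds = lo
            if self.threshold is None:
                self.threshold = 0.8 * float(lo.max(axis=1).sum())

    def __len__(self) -> int:
        return self.length

    def _regex(self, consensus: str) -> re.Pattern:
        return re.compile(
            "(?=(" + "".join(f"[{IUPAC[c]}]" for c in consensus) + "))"
        )


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _scan_consensus(seq: str, motif: MotifModel, both_strands: bool) -> list[tuple[int, str]]:
    hits = [(m.start(), "+") for m in motif._regex(motif.consensus).finditer(seq)]
    if both_strands:
        rc = reverse_complement(motif.consensus)
        hits += [(m.start(), "-") for m in motif._regex(rc).finditer(seq)]
    return hits


def _scan_pwm(seq: str, motif: MotifModel, both_strands: bool) -> list[tuple[int, str, float]]:
    L = motif.length
    if len(seq) < L:
        return []
    idx = np.full(len(seq), -1, dtype=np.int64)
    for base, i in _BASE_IDX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    hits = []
    mats = [("+", motif._logodds)]
    if both_strands:
        mats.append(("-", motif._logodds[::-1, ::-1]))
    n_pos = len(seq) - L + 1
    for strand, lo in mats:
        scores = np.zeros(n_pos)
        valid = np.ones(n_pos, dtype=bool)
        for j in range(L):
            col = idx[j:j + n_pos]
            ok = col >= 0
            valid &= ok
            scores += np.where(ok, lo[j, np.clip(col, 0, 3)], 0.0)
        for i in np.nonzero(valid & (scores >= motif.threshold))[0]:
            hits.append((int(i), strand, float(scores[i])))
    return hits


def scan(seq: str, motif: MotifModel, both_strands: bool = True) -> list[MotifHit]:
    """All motif occurrences in a sequence (offsets are 0-based).

    Hits are reported on a synthetic one-contig coordinate system named '.';
    use :func:`scan_region` for genomic coordinates.
    """
    return scan_region(seq, motif, GenomicInterval(".", 0, max(1, len(seq))),
                       both_strands=both_strands)


def scan_region(
    seq: str,
    motif: MotifModel,
    region: GenomicInterval,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan ``seq`` (the sequence of ``region``) and report genomic hits."""
    seq = seq.upper()
    hits: list[MotifHit] = []
    if motif.length > len(seq):
        return hits
    if motif.consensus is not None:
        for off, strand in _scan_consensus(seq, motif, both_strands):
            hits.append(MotifHit(
                GenomicInterval(region.chrom, region.start + off,
                                region.start + off + motif.length, strand),
                strand, motif.name,
            ))
    else:
        for off, strand, score in _scan_pwm(seq, motif, both_strands):
            hits.append(MotifHit(
                GenomicInterval(region.chrom, region.start + off,
                                region.start + off + motif.length, strand),
                strand, motif.name, score,
            ))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def gc_matched_background(
    targets: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    genome,
    gc_bin_width: float = 0.05,
    seed: int = 0,
) -> IntervalSet:
    """Random background with the targets' GC-content histogram, exactly.

    Windows are bucketed by floor(GC / width); sampling is uniform without
    replacement within each bucket and deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)

    def gc_bin(iv: GenomicInterval) -> int:
        return int(gc_fraction(fetch_sequence(genome, iv)) // gc_bin_width)

    want: dict[int, int] = {}
    for iv in targets:
        b = gc_bin(iv)
        want[b] = want.get(b, 0) + 1
    pool: dict[int, list[GenomicInterval]] = {}
    for iv in universe:
        pool.setdefault(gc_bin(iv), []).append(iv)
    chosen: list[GenomicInterval] = []
    for b in sorted(want):
        avail = pool.get(b, [])
        if len(avail) < want[b]:
            lo = b * gc_bin_width
            raise ValueError(
                f"GC bin [{lo:.2f},{lo + gc_bin_width:.2f}): universe has "
                f"{len(avail)} windows, need {want[b]}"
            )
        idx = rng.choice(len(avail), size=want[b], replace=False)
        chosen.extend(avail[i] for i in idx)
    return IntervalSet(chosen, name="gc_matched_background")


def _hit_fraction(regions: Sequence[GenomicInterval], motif: MotifModel, genome) -> float:
    if not regions:
        return float("nan")
    n = sum(
        1 for iv in regions
        if scan_region(fetch_sequence(genome, iv), motif, iv)
    )
    return n / len(regions)


def enrichment_by_ec(
    regions: Sequence[tuple[GenomicInterval, str]],
    background: Sequence[GenomicInterval],
    motifs: Sequence[MotifModel],
    genome,
) -> pd.DataFrame:
    """Per-motif hit-fraction fold enrichment, overall and split by EC status.

    ``regions`` pairs each window with its 'EC'/'ENC' label.  Fold is the
    ratio of the fraction of windows carrying >= 1 hit to the same fraction in
    the background (NaN when the background fraction is 0); the p-value is a
    Pearson chi-square on the hit/no-hit 2x2 and BH correction runs across
    motifs within each stratum.
    """
    from .enrichment import bh_fdr, chi2_2x2

    strata = {
        "all": [iv for iv, _ in regions],
        "EC": [iv for iv, s in regions if s == "EC"],
        "ENC": [iv for iv, s in regions if s == "ENC"],
    }
    bg_n = len(background)
    rows = []
    for stratum, ivs in strata.items():
        if not ivs:
            continue
        for motif in motifs:
            tf = _hit_fraction(ivs, motif, genome)
            bf = _hit_fraction(background, motif, genome)
            if np.isnan(bf) or bf == 0:
                fold = float("nan")
            else:
                fold = tf / bf
            t_hit = round(tf * len(ivs))
            b_hit = round(bf * bg_n)
            _, p = chi2_2x2([[t_hit, len(ivs) - t_hit], [b_hit, bg_n - b_hit]])
            rows.append({
                "motif": motif.name, "stratum": stratum,
                "n_regions": len(ivs),
                "target_hit_fraction": tf, "background_hit_fraction": bf,
                "fold": fold, "p_value": p,
            })
    df = pd.DataFrame(rows)
    df["q_value"] = np.nan
    for stratum in df["stratum"].unique():
        mask = (df["stratum"] == stratum) & df["p_value"].notna()
        if mask.any():
            df.loc[mask, "q_value"] = bh_fdr(df.loc[mask, "p_value"].to_numpy())
    return df


def classify_turnover(
    src_region: GenomicInterval,
    src_hits: Sequence[MotifHit],
    dst_region: GenomicInterval,
    dst_hits: Sequence[MotifHit],
    chains,
    min_cover: float = 0.5,
    check_orthology: bool = True,
) -> str:
    """Cross-species fate of a motif within an orthologous region pair.

    A source hit counts as conserved in place when its lifted image shares at
    least one base with a destination hit.  Swapping source and destination
    maps LOSS <-> GAIN and fixes the other classes.
    """
    if check_orthology:
        lifted = liftover_interval(chains, src_region, min_cover=min_cover,
                                   max_span=10 * len(src_region))
        if not lifted.mapped or lifted.target.overlap(dst_region) == 0:
            raise ValueError(
                f"{src_region} does not lift onto {dst_region}; "
                "regions are not an ortholog pair under these chains"
            )
    dst_ivs = [h.interval for h in dst_hits]
    for hit in src_hits:
        img = liftover_interval(chains, hit.interval, min_cover=min_cover,
                                max_span=1000)
        if img.mapped and any(img.target.overlap(d) > 0 for d in dst_ivs):
            return CONSERVED_IN_PLACE
    if src_hits and dst_hits:
        return TURNOVER
    if src_hits:
        return LOSS
    if dst_hits:
        return GAIN
    return ABSENT_BOTH


def parse_motif_list(path) -> list[MotifModel]:
    """Read a plain-text motif list: one 'name<TAB>consensus' per line."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 2:
                raise ValueError(f"malformed motif line: {s!r}")
            motifs.append(MotifModel(parts[0], consensus=parts[1]))
    return motifs
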