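"""Coordinate types, interval arithmetic, and plain-text genomics format I/O.

All coordinates are 0-based, half-open (BED convention).  genePred-like gene
tables are consumed with txStart/txEnd already 0-based half-open, matching the
UCSC database dumps.  Chain files follow the UCSC chain format; negative-strand
query coordinates are converted to forward-strand coordinates at parse time
(the original header fields are preserved so a parsed chain can be written back
verbatim).
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "GenomicInterval",
    "IntervalSet",
    "ChainBlock",
    "Chain",
    "GeneRecord",
    "ScoreTrack",
    "overlap_bases",
    "tile_genome",
    "parse_bed",
    "write_bed",
    "parse_chain",
    "write_chain",
    "parse_wig",
    "write_fixedstep_wig",
    "parse_genepred",
    "write_genepred",
    "parse_chrom_sizes",
    "write_chrom_sizes",
    "fetch_sequence",
]

_SKIP = ("#", "track", "browser")


class FormatError(ValueError):
    """Raised when a text input violates its declared format."""


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or any(s.startswith(p) for p in _SKIP)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open region on a named contig."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("contig name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 on different contigs)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    May contain overlaps unless :meth:`flatten`-ed.  Each interval can carry an
    opaque tuple of extra string columns (``extras``), preserved verbatim by
    the BED reader/writer.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        name: str = "",
        extras: Sequence[tuple] | None = None,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.name = name
        if extras is None:
            self.extras: list[tuple] = [() for _ in self.intervals]
        else:
            self.extras = [tuple(e) for e in extras]
            if len(self.extras) != len(self.intervals):
                raise ValueError("extras must parallel intervals")
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def append(self, iv: GenomicInterval, extra: tuple = ()) -> None:
        self.intervals.append(iv)
        self.extras.append(tuple(extra))
        self._index = None

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted(self) -> "IntervalSet":
        order = sorted(range(len(self.intervals)), key=lambda i: self.intervals[i].sort_key())
        return IntervalSet(
            [self.intervals[i] for i in order],
            name=self.name,
            extras=[self.extras[i] for i in order],
        )

    def flatten(self) -> "IntervalSet":
        """Merge overlapping/abutting intervals per contig; drops strand/extras."""
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        merged: list[GenomicInterval] = []
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    merged.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
        return IntervalSet(merged, name=self.name)

    def coverage_index(self) -> Mapping[str, tuple[np.ndarray, np.ndarray]]:
        """Per-contig (starts, ends) arrays of the flattened set, cached."""
        if self._index is None:
            idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            flat = self.flatten()
            by_chrom: dict[str, list[GenomicInterval]] = {}
            for iv in flat:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            for chrom, ivs in by_chrom.items():
                idx[chrom] = (
                    np.array([iv.start for iv in ivs], dtype=np.int64),
                    np.array([iv.end for iv in ivs], dtype=np.int64),
                )
            self._index = idx
        return self._index

    def total_bases(self) -> int:
        return sum(int((e - s).sum()) for s, e in self.coverage_index().values())


def overlap_bases(a: GenomicInterval, s: IntervalSet) -> int:
    """Bases of ``a`` covered by the (flattened) set ``s``.

    Each base of ``a`` is counted at most once regardless of how many raw
    intervals of ``s`` cover it.
    """
    idx = s.coverage_index()
    if a.chrom not in idx:
        return 0
    starts, ends = idx[a.chrom]
    ov = np.minimum(ends, a.end) - np.maximum(starts, a.start)
    return int(np.clip(ov, 0, None).sum())


def tile_genome(index: Mapping[str, int], window: int = 500) -> IntervalSet:
    """Left-aligned non-overlapping windows per contig.

    A trailing remainder shorter than ``window`` is dropped, so every emitted
    window has exactly ``window`` bases.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    tiles: list[GenomicInterval] = []
    for chrom in index:
        length = index[chrom]
        if length <= 0:
            raise ValueError(f"contig {chrom} has non-positive length")
        for start in range(0, length - window + 1, window):
            tiles.append(GenomicInterval(chrom, start, start + window))
    return IntervalSet(tiles, name=f"tiles_{window}bp")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def parse_bed(path, min_cols: int = 3) -> IntervalSet:
    """Read BED3+ into an :class:`IntervalSet`.

    Columns beyond the third are preserved as strings in ``extras``.  When a
    sixth column holding a strand is present it is also reflected in the
    interval's ``strand`` attribute.
    """
    out = IntervalSet(name=Path(path).stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            cols = line.rstrip("\n").split("\t") if "\t" in line else line.split()
            if len(cols) < min_cols or len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= {max(min_cols, 3)} columns")
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = "."
            if len(cols) >= 6 and cols[5] in ("+", "-"):
                strand = cols[5]
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv, tuple(cols[3:]))
    return out


def write_bed(iset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv, extra in zip(iset.intervals, iset.extras):
            cols = [iv.chrom, str(iv.start), str(iv.end), *extra]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainBlock:
    """One ungapped alignment block: ``size`` aligned bases then gaps of
    ``dt`` on the target and ``dq`` on the query before the next block."""

    size: int
    dt: int = 0
    dq: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("block size must be positive")
        if self.dt < 0 or self.dq < 0:
            raise ValueError("gaps must be non-negative")


@dataclass
class Chain:
    """A UCSC chain alignment.

    ``t_*`` fields describe the target (source assembly) side, ``q_*`` the
    query side, exactly as in the file.  When ``q_strand == '-'`` the file's
    query coordinates count from the reverse-complemented query; internal
    per-block arrays are normalized to forward-strand query coordinates.
    """

    id: int
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[ChainBlock]

    # forward-strand block geometry, filled by _finalize()
    _t_starts: np.ndarray = field(default=None, repr=False, compare=False)
    _sizes: np.ndarray = field(default=None, repr=False, compare=False)
    _q_los: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._finalize()

    def _finalize(self) -> None:
        tsum = sum(b.size + b.dt for b in self.blocks)
        qsum = sum(b.size + b.dq for b in self.blocks)
        if self.blocks and (self.blocks[-1].dt or self.blocks[-1].dq):
            raise FormatError(f"chain {self.id}: last block must have zero gaps")
        if tsum != self.t_end - self.t_start:
            raise FormatError(
                f"chain {self.id}: block sizes+target gaps ({tsum}) != "
                f"target span ({self.t_end - self.t_start})"
            )
        if qsum != self.q_end - self.q_start:
            raise FormatError(
                f"chain {self.id}: block sizes+query gaps ({qsum}) != "
                f"query span ({self.q_end - self.q_start})"
            )
        if self.q_strand not in ("+", "-"):
            raise FormatError(f"chain {self.id}: bad query strand {self.q_strand!r}")
        t_starts, sizes, q_los = [], [], []
        t = self.t_start
        q = self.q_start  # native (strand-local) coordinate
        for b in self.blocks:
            t_starts.append(t)
            sizes.append(b.size)
            if self.q_strand == "+":
                q_los.append(q)
            else:
                q_los.append(self.q_size - (q + b.size))
            t += b.size + b.dt
            q += b.size + b.dq
        self._t_starts = np.array(t_starts, dtype=np.int64)
        self._sizes = np.array(sizes, dtype=np.int64)
        self._q_los = np.array(q_los, dtype=np.int64)

    @property
    def t_span(self) -> int:
        return self.t_end - self.t_start

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    def block_images(self) -> Iterator[tuple[int, int, int]]:
        """Yield (t_start, size, q_lo_forward) for each block."""
        for tb, sz, ql in zip(self._t_starts, self._sizes, self._q_los):
            yield int(tb), int(sz), int(ql)

    def map_point(self, pos: int) -> int | None:
        """Forward-strand query image of a target base, or None if in a gap."""
        i = bisect_right(self._t_starts, pos) - 1
        if i < 0:
            return None
        tb, sz, ql = int(self._t_starts[i]), int(self._sizes[i]), int(self._q_los[i])
        if pos >= tb + sz:
            return None
        off = pos - tb
        if self.q_strand == "+":
            return ql + off
        return ql + sz - 1 - off

    def aligned_overlap(self, start: int, end: int) -> int:
        """Aligned (in-block) bases of target interval [start, end)."""
        lo = np.maximum(self._t_starts, start)
        hi = np.minimum(self._t_starts + self._sizes, end)
        return int(np.clip(hi - lo, 0, None).sum())


def parse_chain(path) -> list[Chain]:
    """Parse a UCSC chain file; validates block-sum invariants per chain."""
    chains: list[Chain] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []
    auto_id = 0

    def finish() -> None:
        nonlocal header, blocks, auto_id
        if header is None:
            return
        (
            _, score, t_name, t_size, t_strand, t_start, t_end,
            q_name, q_size, q_strand, q_start, q_end, *rest
        ) = header
        if t_strand != "+":
            raise FormatError(f"chain target strand must be '+', got {t_strand!r}")
        auto_id += 1
        cid = int(rest[0]) if rest else auto_id
        chain_blocks = [ChainBlock(s, dt, dq) for s, dt, dq in blocks]
        chains.append(
            Chain(
                id=cid,
                score=float(score),
                t_name=t_name,
                t_size=int(t_size),
                t_start=int(t_start),
                t_end=int(t_end),
                q_name=q_name,
                q_size=int(q_size),
                q_strand=q_strand,
                q_start=int(q_start),
                q_end=int(q_end),
                blocks=chain_blocks,
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("chain"):
                finish()
                header = s.split()
                if len(header) < 12:
                    raise FormatError(f"{path}:{lineno}: truncated chain header")
                continue
            if header is None:
                raise FormatError(f"{path}:{lineno}: block line outside a chain")
            parts = s.split()
            if len(parts) == 1:
                blocks.append((int(parts[0]), 0, 0))
            elif len(parts) == 3:
                blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
            else:
                raise FormatError(f"{path}:{lineno}: malformed block line")
    finish()
    return chains


def write_chain(chains: Iterable[Chain], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.dt} {b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


# ---------------------------------------------------------------------------
# Gene tables (genePred-like)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """A transcript record.  The TSS coordinate is txStart on '+' and txEnd
    on '-' (UCSC convention for the 5' end of the transcript)."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None = None
    cds_end: int | None = None
    exon_starts: tuple[int, ...] = ()
    exon_ends: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"gene {self.name}: txStart >= txEnd")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be + or -")
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {self.name}: exon outside transcript")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


def parse_genepred(path) -> list[GeneRecord]:
    """Read a genePred-like table: name chrom strand txStart txEnd
    [cdsStart cdsEnd exonCount exonStarts exonEnds]."""
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 columns")
            name, chrom, strand = cols[0], cols[1], cols[2]
            tx_start, tx_end = int(cols[3]), int(cols[4])
            cds_start = cds_end = None
            exon_starts: tuple[int, ...] = ()
            exon_ends: tuple[int, ...] = ()
            if len(cols) >= 7:
                cds_start, cds_end = int(cols[5]), int(cols[6])
            if len(cols) >= 10:
                exon_starts = tuple(int(x) for x in cols[8].rstrip(",").split(",") if x)
                exon_ends = tuple(int(x) for x in cols[9].rstrip(",").split(",") if x)
            try:
                genes.append(
                    GeneRecord(name, chrom, strand, tx_start, tx_end,
                               cds_start, cds_end, exon_starts, exon_ends)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_genepred(genes: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            cds_s = g.cds_start if g.cds_start is not None else g.tx_start
            cds_e = g.cds_end if g.cds_end is not None else g.tx_end
            starts = ",".join(str(x) for x in g.exon_starts) + ","
            ends = ",".join(str(x) for x in g.exon_ends) + ","
            fh.write(
                f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t"
                f"{cds_s}\t{cds_e}\t{len(g.exon_starts)}\t{starts}\t{ends}\n"
            )


# ---------------------------------------------------------------------------
# Per-base score tracks (wig)
# ---------------------------------------------------------------------------

class ScoreTrack:
    """Sparse per-base numeric scores: a list of dense segments per contig.

    Absent positions carry no data; queries report only covered bases unless a
    fill value is requested.
    """

    def __init__(self) -> None:
        self._segments: dict[str, list[tuple[int, np.ndarray]]] = {}

    def add_segment(self, chrom: str, start: int, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=np.float64)
        if not np.isfinite(values).all():
            raise ValueError("score values must be finite")
        if start < 0:
            raise ValueError("segment start must be >= 0")
        self._segments.setdefault(chrom, []).append((start, values))
        self._segments[chrom].sort(key=lambda t: t[0])

    @property
    def contigs(self) -> list[str]:
        return sorted(self._segments)

    def segments(self, chrom: str) -> list[tuple[int, np.ndarray]]:
        return self._segments.get(chrom, [])

    def values(self, iv: GenomicInterval, fill: float = np.nan) -> np.ndarray:
        """Per-base values over ``iv``; uncovered bases get ``fill``."""
        out = np.full(len(iv), fill, dtype=np.float64)
        for start, vals in self._segments.get(iv.chrom, []):
            end = start + len(vals)
            lo = max(start, iv.start)
            hi = min(end, iv.end)
            if lo < hi:
                out[lo - iv.start:hi - iv.start] = vals[lo - start:hi - start]
        return out

    def mean(self, iv: GenomicInterval) -> float:
        """Mean score over covered bases of ``iv`` (NaN if none covered)."""
        v = self.values(iv)
        good = np.isfinite(v)
        if not good.any():
            return float("nan")
        return float(v[good].mean())


_WIG_FIXED = re.compile(r"fixedStep\s+chrom=(\S+)\s+start=(\d+)(?:\s+step=(\d+))?(?:\s+span=(\d+))?")
_WIG_VAR = re.compile(r"variableStep\s+chrom=(\S+)(?:\s+span=(\d+))?")


def parse_wig(path) -> ScoreTrack:
    """Read fixed-step or variable-step wiggle into a :class:`ScoreTrack`.

    Wiggle ``start`` coordinates are 1-based; they are converted to 0-based
    here.  ``step``/``span`` default to 1.
    """
    track = ScoreTrack()
    mode = None  # ("fixed", chrom, next_pos, step, span) | ("var", chrom, span)
    buf_start = 0
    buf: list[str] = []  # raw value strings; converted in bulk on flush
    buf_span = 1
    buf_chrom = ""

    def flush() -> None:
        nonlocal buf
        if buf:
            vals = np.asarray(buf, dtype=np.float64)
            if buf_span > 1:
                vals = np.repeat(vals, buf_span)
            track.add_segment(buf_chrom, buf_start, vals)
        buf = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("track") or s.startswith("browser"):
                continue
            m = _WIG_FIXED.match(s)
            if m:
                flush()
                chrom, start1, step, span = m.group(1), int(m.group(2)), m.group(3), m.group(4)
                step = int(step) if step else 1
                span = int(span) if span else 1
                mode = ["fixed", chrom, start1 - 1, step, span]
                buf_chrom, buf_start, buf_span = chrom, start1 - 1, span
                continue
            m = _WIG_VAR.match(s)
            if m:
                flush()
                chrom, span = m.group(1), int(m.group(2)) if m.group(2) else 1
                mode = ["var", chrom, span]
                buf_chrom = chrom
                continue
            if mode is None:
                raise FormatError(f"{path}:{lineno}: data before any step declaration")
            if mode[0] == "fixed":
                _, chrom, pos, step, span = mode
                if step == span:
                    if not buf:
                        buf_start = pos
                    buf.append(s)
                else:
                    flush()
                    track.add_segment(chrom, pos, np.full(span, float(s)))
                mode[2] = pos + step
            else:
                _, chrom, span = mode
                parts = s.split()
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: malformed variableStep line")
                pos = int(parts[0]) - 1
                track.add_segment(chrom, pos, np.full(span, float(parts[1])))
    flush()
    return track


def write_fixedstep_wig(track: ScoreTrack, path, precision: int = 3) -> None:
    with open(path, "w") as fh:
        for chrom in track.contigs:
            for start, vals in track.segments(chrom):
                fh.write(f"fixedStep chrom={chrom} start={start + 1} step=1\n")
                np.savetxt(fh, vals, fmt=f"%.{precision}f")


# ---------------------------------------------------------------------------
# Misc small formats
# ---------------------------------------------------------------------------

def parse_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if _is_skippable(line):
                continue
            chrom, length = line.split()[:2]
            sizes[chrom] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def fetch_sequence(genome, iv: GenomicInterval) -> str:
    """Uppercase sequence of ``iv`` from a pyfaidx.Fasta or a plain mapping
    of contig name to string."""
    seq = genome[iv.chrom]
    if isinstance(seq, str):
        return seq[iv.start:iv.end].upper()
    return str(seq[iv.start:iv.end]).upper()
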