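"""Chain-based liftover and three-way ortholog construction.

Interval liftover maps a source-assembly interval through the single best
(highest-scoring) chain whose aligned blocks touch it, with two acceptance
rules: at least ``min_cover`` (default 50%) of the source bases must fall in
aligned blocks, and the image envelope on the other assembly may span at most
``max_span`` bases (default 1000).  Failing either rule yields an unmapped
result, not an error.

A chain is a candidate for an interval only if at least one aligned base of
the chain overlaps the interval — an interval sitting entirely inside a chain
gap falls through to lower-scoring chains, mirroring how UCSC liftOver picks
among overlapping chains.  Ties on score break toward the lowest chain id, so
mapping is deterministic.

Three-way orthologs reconcile a direct source->C mapping with the composed
source->B->C path and require the two C-side images to overlap by at least 90%
of the shorter image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from .intervals import Chain, GenomicInterval, parse_chain

__all__ = [
    "LiftoverResult",
    "ThreeWayOrtholog",
    "PointImage",
    "ChainSet",
    "liftover_interval",
    "liftover_point",
    "build_threeway",
]


@dataclass(frozen=True)
class LiftoverResult:
    """Outcome of lifting one interval.

    ``covered_fraction`` is mapped source bases / source length on the chosen
    chain; ``target`` is the envelope of the mapped bases' images, or None when
    the coverage or span rule rejected the mapping (or no chain touched the
    interval, in which case ``chain_id`` is None too).
    """

    source: GenomicInterval
    target: GenomicInterval | None
    covered_fraction: float
    chain_id: int | None

    @property
    def mapped(self) -> bool:
        return self.target is not None


class PointImage(NamedTuple):
    chrom: str
    pos: int
    strand: str


@dataclass(frozen=True)
class ThreeWayOrtholog:
    rat: GenomicInterval
    mouse: GenomicInterval
    human: GenomicInterval
    reconciliation_overlap: float


class ChainSet:
    """A chain file in memory, indexed by target (source-assembly) contig."""

    def __init__(self, chains: Iterable[Chain]) -> None:
        self.chains = list(chains)
        self._by_tname: dict[str, list[Chain]] = {}
        for c in self.chains:
            self._by_tname.setdefault(c.t_name, []).append(c)
        self.by_id = {c.id: c for c in self.chains}

    @classmethod
    def from_file(cls, path) -> "ChainSet":
        return cls(parse_chain(path))

    def candidates(self, iv: GenomicInterval) -> list[Chain]:
        """Chains with >= 1 aligned base inside ``iv``."""
        return [
            c for c in self._by_tname.get(iv.chrom, [])
            if c.t_start < iv.end and c.t_end > iv.start
            and c.aligned_overlap(iv.start, iv.end) > 0
        ]

    def best_chain(self, iv: GenomicInterval) -> Chain | None:
        cands = self.candidates(iv)
        if not cands:
            return None
        return min(cands, key=lambda c: (-c.score, c.id))


def _coerce(chains) -> ChainSet:
    if isinstance(chains, ChainSet):
        return chains
    return ChainSet(chains)


def liftover_interval(
    chains,
    iv: GenomicInterval,
    min_cover: float = 0.5,
    max_span: int = 1000,
) -> LiftoverResult:
    """Map ``iv`` through the best chain; see module docstring for the rules."""
    cs = _coerce(chains)
    chain = cs.best_chain(iv)
    if chain is None:
        return LiftoverResult(iv, None, 0.0, None)
    covered = 0
    env_lo = None
    env_hi = None
    for tb, sz, q_lo in chain.block_images():
        a = max(tb, iv.start)
        b = min(tb + sz, iv.end)
        if a >= b:
            continue
        covered += b - a
        if chain.q_strand == "+":
            lo = q_lo + (a - tb)
            hi = q_lo + (b - tb)
        else:
            lo = q_lo + sz - (b - tb)
            hi = q_lo + sz - (a - tb)
        env_lo = lo if env_lo is None else min(env_lo, lo)
        env_hi = hi if env_hi is None else max(env_hi, hi)
    frac = covered / len(iv)
    if frac < min_cover or env_lo is None or (env_hi - env_lo) > max_span:
        return LiftoverResult(iv, None, frac, chain.id)
    target = GenomicInterval(chain.q_name, env_lo, env_hi, chain.q_strand)
    return LiftoverResult(iv, target, frac, chain.id)


def liftover_point(chains, chrom: str, pos: int) -> PointImage | None:
    """Image of a single base, or None when it lies in a gap of every chain
    touching it."""
    cs = _coerce(chains)
    best: tuple[tuple[float, int], PointImage] | None = None
    for c in cs._by_tname.get(chrom, []):
        if not (c.t_start <= pos < c.t_end):
            continue
        q = c.map_point(pos)
        if q is None:
            continue
        key = (-c.score, c.id)
        if best is None or key < best[0]:
            best = (key, PointImage(c.q_name, q, c.q_strand))
    return best[1] if best else None


def build_threeway(
    src_to_b: Mapping[GenomicInterval, LiftoverResult] | Sequence[LiftoverResult],
    src_to_c: Mapping[GenomicInterval, LiftoverResult] | Sequence[LiftoverResult],
    b_to_c_chains,
    min_recip: float = 0.9,
    min_cover: float = 0.5,
    max_span: int = 1000,
) -> list[ThreeWayOrtholog]:
    """Reconcile direct and composed mappings into three-way orthologs.

    For each source region mapped in both B (mouse) and C (human), the B image
    is lifted to C and compared with the direct C image; the triple is accepted
    when the two C images overlap by >= ``min_recip`` of the shorter one.
    """
    def as_map(x):
        if isinstance(x, Mapping):
            return dict(x)
        return {r.source: r for r in x}

    m_b = as_map(src_to_b)
    m_c = as_map(src_to_c)
    cs = _coerce(b_to_c_chains)
    out: list[ThreeWayOrtholog] = []
    for src, rb in m_b.items():
        rc = m_c.get(src)
        if rc is None or not rb.mapped or not rc.mapped:
            continue
        via = liftover_interval(cs, rb.target, min_cover=min_cover, max_span=max_span)
        if not via.mapped:
            continue
        shorter = min(len(rc.target), len(via.target))
        frac = rc.target.overlap(via.target) / shorter
        if frac >= min_recip:
            out.append(ThreeWayOrtholog(src, rb.target, rc.target, frac))
    return out
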