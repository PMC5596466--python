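"""Shared fixtures and independent oracles.

The liftover oracle here deliberately re-derives block geometry from the raw
chain header/block fields by per-base enumeration, independent of the
package's normalized block arrays.
"""

from __future__ import annotations

import numpy as np
import pytest

from epicons import SimulationConfig, simulate_trio
from epicons.intervals import Chain, ChainBlock


# ---------------------------------------------------------------------------
# random chains and a per-base brute-force liftover oracle
# ---------------------------------------------------------------------------

def random_chain(rng: np.random.Generator, cid: int,
                 t_name: str = "chrA", q_name: str = "chrB",
                 t_size: int = 100_000, q_size: int = 100_000) -> Chain:
    """A random valid chain with span <= ~100 kb, possibly '-' stranded."""
    n_blocks = int(rng.integers(1, 9))
    blocks = []
    for i in range(n_blocks):
        size = int(rng.integers(1, 201))
        if i == n_blocks - 1:
            blocks.append(ChainBlock(size))
        else:
            blocks.append(ChainBlock(size, int(rng.integers(0, 101)),
                                     int(rng.integers(0, 101))))
    t_span = sum(b.size + b.dt for b in blocks)
    q_span = sum(b.size + b.dq for b in blocks)
    t_start = int(rng.integers(0, t_size - t_span))
    q_start = int(rng.integers(0, q_size - q_span))
    q_strand = "+" if rng.random() < 0.5 else "-"
    return Chain(
        id=cid, score=float(rng.integers(1, 10_000)),
        t_name=t_name, t_size=t_size, t_start=t_start, t_end=t_start + t_span,
        q_name=q_name, q_size=q_size, q_strand=q_strand,
        q_start=q_start, q_end=q_start + q_span, blocks=blocks,
    )


def oracle_base_image(chain: Chain, pos: int) -> int | None:
    """Forward-strand query image of one target base, by walking the raw
    block list base by base."""
    t = chain.t_start
    q = chain.q_start  # native coordinate
    for b in chain.blocks:
        for k in range(b.size):
            if t + k == pos:
                native = q + k
                if chain.q_strand == "+":
                    return native
                return chain.q_size - 1 - native
        t += b.size + b.dt
        q += b.size + b.dq
    return None


def oracle_point(chains, chrom: str, pos: int):
    """(q_name, image) through the best chain whose blocks contain pos."""
    best = None
    for c in chains:
        if c.t_name != chrom:
            continue
        img = oracle_base_image(c, pos)
        if img is None:
            continue
        key = (-c.score, c.id)
        if best is None or key < best[0]:
            best = (key, (c.q_name, img))
    return best[1] if best else None


def oracle_interval(chains, iv, min_cover: float = 0.5, max_span: int = 1000):
    """(target (chrom, lo, hi) or None, covered_fraction, chain_id or None)
    by per-base enumeration, mirroring the single-best-chain rule."""
    candidates = []
    for c in chains:
        if c.t_name != iv.chrom:
            continue
        images = [oracle_base_image(c, p) for p in range(iv.start, iv.end)]
        images = [x for x in images if x is not None]
        if images:
            candidates.append((( -c.score, c.id), c, images))
    if not candidates:
        return None, 0.0, None
    key, chain, images = min(candidates, key=lambda t: t[0])
    frac = len(images) / len(iv)
    lo, hi = min(images), max(images) + 1
    if frac < min_cover or (hi - lo) > max_span:
        return None, frac, chain.id
    return (chain.q_name, lo, hi), frac, chain.id


# ---------------------------------------------------------------------------
# simulated bundles
# ---------------------------------------------------------------------------

SMALL_CONFIG = dict(
    seed=13, n_contigs=1, contig_length=200_000, n_dmrs_per_tissue=40,
    n_unmethylated_windows=20, n_background_elements=30,
    n_background_peaks=30, n_genes_per_contig=8,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("trio_small")
    return simulate_trio(SimulationConfig(**SMALL_CONFIG), out)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    from epicons.pipeline import run_trio

    return run_trio(small_bundle, curve_bins=20)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default-scale trio used for parameter-recovery checks."""
    out = tmp_path_factory.mktemp("trio_default")
    return simulate_trio(SimulationConfig(seed=7), out)


@pytest.fixture(scope="session")
def default_result(default_bundle):
    from epicons.pipeline import run_trio

    return run_trio(default_bundle)
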