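"""Synthetic three-species benchmark with full ground truth.

Generates a "rat" reference genome plus "mouse" and "human" genomes related to
it by block alignments (conserved blocks separated by small species-specific
insertions/deletions, with per-base substitutions inside blocks), together
with everything the comparative pipeline consumes:

* per-tissue CpG methylation bedGraphs for all three species, with planted
  tissue-specific hypomethylated windows, a configurable fraction of which
  repeat the tissue pattern in mouse/human (epigenetic conservation);
* pairwise UCSC chain files (rat-mouse, rat-human, mouse-human) that are
  mutually consistent except for deliberately rearranged blocks;
* gene tables, CpG-island and repeat BEDs, conserved-element BEDs coupled to
  the planted conservation status, per-base score wigs whose level is coupled
  to conservation status, and histone peak BEDs whose summits fall in
  conserved regions at a configured rate;
* transcription-factor motif instances planted with known cross-species fates
  (conserved in place, turnover, loss).

Everything is drawn from one seeded generator, so a config yields a
byte-identical bundle every time.  The truth table records, per planted
region, its coordinates in all three species, tissue, conservation flags and
motif/peak/element events, enabling exact recovery scoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    Chain,
    ChainBlock,
    GeneRecord,
    GenomicInterval,
    IntervalSet,
    ScoreTrack,
    parse_chrom_sizes,
    write_bed,
    write_chain,
    write_chrom_sizes,
    write_fixedstep_wig,
    write_genepred,
)
from .motifs import IUPAC, MotifModel
from .orthology import ChainSet

__all__ = ["SimulationConfig", "TrioBundle", "simulate_trio", "recovery_report"]

SPECIES = ("rat", "mouse", "human")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic trio; every field has a fixed default so a
    seed alone specifies a bundle."""

    seed: int
    n_contigs: int = 2
    contig_length: int = 1_000_000
    cpg_rate: float = 0.02              # CpG sites per bp (Poisson-like)
    block_mean_length: int = 1_500      # conserved alignment block mean, bp
    gap_mean_length: int = 40           # indel (chain gap) mean, bp
    substitution_rate: float = 0.05     # per-base within aligned blocks
    tissues: tuple = ("blood", "brain", "sperm")
    n_dmrs_per_tissue: int = 300
    dmr_length: int = 500
    intermediate_fraction: float = 0.1  # criterion-2 (intermediate) tsDMRs
    p_ec_mouse: float = 0.3
    p_ec_human: float = 0.15
    p_ortholog_retained: float = 0.9    # block kept in BOTH other species
    hypo_mean: float = 0.1
    intermediate_mean: float = 0.5
    hyper_mean: float = 0.85
    level_sd: float = 0.05
    n_unmethylated_windows: int = 100   # hypo in all tissues (CGI-like)
    motifs: tuple = (
        ("Erg", "ACAGGAAGTG"),
        ("Fli1", "TCAGGAAGCC"),
        ("Lhx3", "CTAATTAATT"),
    )
    p_motif_in_ec: float = 0.8
    p_motif_in_enc: float = 0.1
    p_motif_background: float = 0.05
    p_turnover_given_motif: float = 0.2
    p_loss_given_motif: float = 0.1
    element_overlap_rate_ec: float = 0.6
    element_overlap_rate_enc: float = 0.2
    n_background_elements: int = 150    # per contig
    peak_rate_ec: float = 0.6
    peak_rate_enc: float = 0.2
    n_background_peaks: int = 150       # per species x tissue
    score_coupling: float = 1.5         # score shift of EC regions
    score_region_sd: float = 0.75       # per-region score jitter
    score_base_sd: float = 0.3          # per-base score noise
    n_rearranged_blocks: int = 0
    n_genes_per_contig: int = 25
    q_planted: float = 1e-9
    q_background: float = 0.5

    def __post_init__(self) -> None:
        probs = [
            self.cpg_rate, self.intermediate_fraction, self.p_ec_mouse,
            self.p_ec_human, self.p_ortholog_retained, self.p_motif_in_ec,
            self.p_motif_in_enc, self.p_motif_background,
            self.p_turnover_given_motif, self.p_loss_given_motif,
            self.element_overlap_rate_ec, self.element_overlap_rate_enc,
            self.peak_rate_ec, self.peak_rate_enc,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.p_turnover_given_motif + self.p_loss_given_motif > 1.0:
            raise ValueError("turnover + loss probabilities exceed 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.tissues) != 3:
            raise ValueError("exactly 3 tissues required")
        if self.dmr_length != 500:
            raise ValueError("dmr_length must be 500 (window size)")

    def motif_models(self) -> list[MotifModel]:
        return [MotifModel(n, consensus=c) for n, c in self.motifs]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["tissues"] = list(self.tissues)
        d["motifs"] = [list(m) for m in self.motifs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["tissues"] = tuple(d["tissues"])
        d["motifs"] = tuple(tuple(m) for m in d["motifs"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Bundle access
# ---------------------------------------------------------------------------

class TrioBundle:
    """Handle onto an emitted simulation directory."""

    def __init__(self, root) -> None:
        self.root = Path(root)
        self.config = SimulationConfig.from_yaml(self.root / "config.yaml")

    def truth(self) -> pd.DataFrame:
        return pd.read_csv(self.root / "truth.tsv", sep="\t")

    def chrom_sizes(self, species: str) -> dict[str, int]:
        return parse_chrom_sizes(self.root / species / "chrom.sizes")

    def methylomes(self, species: str):
        from .methylome import MethylomeTrack

        return {
            t: MethylomeTrack.from_bedgraph(
                self.root / species / f"meth_{t}.bedgraph", species, t)
            for t in self.config.tissues
        }

    def chains(self, pair: str) -> ChainSet:
        return ChainSet.from_file(self.root / "chains" / f"{pair}.chain")

    def genome(self, species: str):
        import pyfaidx

        return pyfaidx.Fasta(str(self.root / species / "genome.fa"))

    def elements(self) -> IntervalSet:
        from .intervals import parse_bed

        return parse_bed(self.root / "rat" / "conserved_elements.bed")

    def genes(self, species: str):
        from .intervals import parse_genepred

        return parse_genepred(self.root / species / "genes.genepred")

    def annotation(self, species: str = "rat"):
        from .enrichment import AnnotationBundle
        from .intervals import parse_bed

        return AnnotationBundle(
            self.genes(species),
            cgi=parse_bed(self.root / species / "cgi.bed"),
            repeats=parse_bed(self.root / species / "repeats.bed"),
        )

    def score_track(self, species: str) -> ScoreTrack:
        from .intervals import parse_wig

        return parse_wig(self.root / species / "scores.wig")

    def peaks(self, species: str, tissue: str):
        from .enrichment import parse_peaks

        return parse_peaks(self.root / species / f"peaks_{tissue}.bed")


# ---------------------------------------------------------------------------
# Generator internals
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.int8)


def _choose_cpgs(rng, length: int, rate: float) -> np.ndarray:
    cand = np.nonzero(rng.random(length - 2) < rate)[0] + 1
    keep = []
    last = -2
    for p in cand:
        if p - last >= 2:
            keep.append(int(p))
            last = int(p)
    return np.array(keep, dtype=np.int64)


def _geom(rng, mean: int) -> int:
    return 1 + int(rng.geometric(1.0 / mean))


def _make_blocks(rng, length: int, block_mean: int, gap_mean: int):
    """Partition a rat contig into conserved blocks separated by rat-only
    gaps; returns list of (start, length)."""
    blocks = []
    pos = 10
    while True:
        blen = max(300, int(rng.exponential(block_mean)))
        if pos + blen > length - 10:
            blen = length - 10 - pos
            if blen >= 300:
                blocks.append((pos, blen))
            break
        blocks.append((pos, blen))
        pos += blen + _geom(rng, gap_mean)
    return blocks


def _chain_from_pairs(pairs, t_name, t_size, q_name, q_size, score, cid) -> Chain:
    blocks = []
    for i, (ts, qs, sz) in enumerate(pairs):
        if i + 1 < len(pairs):
            nts, nqs, _ = pairs[i + 1]
            blocks.append(ChainBlock(sz, nts - (ts + sz), nqs - (qs + sz)))
        else:
            blocks.append(ChainBlock(sz))
    return Chain(
        id=cid, score=score, t_name=t_name, t_size=t_size,
        t_start=pairs[0][0], t_end=pairs[-1][0] + pairs[-1][2],
        q_name=q_name, q_size=q_size, q_strand="+",
        q_start=pairs[0][1], q_end=pairs[-1][1] + pairs[-1][2],
        blocks=blocks,
    )


def _realize_consensus(consensus: str) -> str:
    # concrete sequence matching the consensus (first base of each class)
    return "".join(IUPAC[c][0] for c in consensus)


def _breaking_base(consensus_char: str, current: str) -> str:
    allowed = set(IUPAC[consensus_char])
    for b in "GATC":
        if b not in allowed and b != current:
            return b
    raise ValueError(f"cannot break consensus position {consensus_char!r}")


def _write_motif(seq: np.ndarray, offset: int, text: str) -> None:
    for i, ch in enumerate(text):
        seq[offset + i] = _IDX[ch]


def _sample_clear(rng, length: int, n: int, len_lo: int, len_hi: int,
                  forb_starts: np.ndarray, forb_ends: np.ndarray,
                  max_tries: int = 50):
    """Random intervals avoiding a disjoint sorted forbidden set."""
    out = []
    for _ in range(n):
        for _ in range(max_tries):
            ln = int(rng.integers(len_lo, len_hi + 1))
            s = int(rng.integers(0, max(1, length - ln)))
            i = np.searchsorted(forb_starts, s + ln)
            if i > 0 and forb_ends[i - 1] > s:
                continue
            out.append((s, s + ln))
            break
    return out


def _write_fasta(path, contigs: Mapping[str, np.ndarray]) -> None:
    with open(path, "wb") as fh:
        for name, idx in contigs.items():
            fh.write(f">{name}\n".encode())
            ascii_arr = _BASES[idx].tobytes()
            for i in range(0, len(ascii_arr), 80):
                fh.write(ascii_arr[i:i + 80])
                fh.write(b"\n")


def simulate_trio(config: SimulationConfig, out_dir) -> TrioBundle:
    """Emit the full synthetic bundle under ``out_dir``; see module docs."""
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    for sub in ("rat", "mouse", "human", "chains"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    L = config.contig_length
    contigs = [f"chr{i + 1}" for i in range(config.n_contigs)]
    tissues = list(config.tissues)
    motif_models = {n: MotifModel(n, consensus=c) for n, c in config.motifs}
    motif_names = [n for n, _ in config.motifs]

    # -- pass 1: rat genome, CpGs, block structure, eligible windows --------
    rat_seq: dict[str, np.ndarray] = {}
    rat_cpg: dict[str, np.ndarray] = {}
    blocks: dict[str, list[tuple[int, int]]] = {}
    eligible: list[tuple[str, int, int]] = []  # (contig, window_start, block_idx)
    for c in contigs:
        rat_seq[c] = _random_seq(rng, L)
        cpgs = _choose_cpgs(rng, L, config.cpg_rate)
        for p in cpgs:
            rat_seq[c][p] = _IDX["C"]
            rat_seq[c][p + 1] = _IDX["G"]
        rat_cpg[c] = cpgs
        blocks[c] = _make_blocks(rng, L, config.block_mean_length,
                                 config.gap_mean_length)
        for bi, (bs, blen) in enumerate(blocks[c]):
            w0 = -(-bs // 500)            # first window fully inside block
            w1 = (bs + blen) // 500       # one past last
            for w in range(w0, w1):
                ws = w * 500
                n_cpg = np.searchsorted(cpgs, ws + 500) - np.searchsorted(cpgs, ws)
                if n_cpg >= 4:
                    eligible.append((c, ws, bi))

    n_dmr_total = 3 * config.n_dmrs_per_tissue
    n_total = n_dmr_total + config.n_unmethylated_windows
    if n_total > len(eligible):
        raise ValueError(
            f"infeasible config: {n_total} planted windows requested but only "
            f"{len(eligible)} eligible windows exist"
        )
    pick = rng.choice(len(eligible), size=n_total, replace=False)
    dmr_rows = []
    for k, idx in enumerate(pick[:n_dmr_total]):
        c, ws, bi = eligible[idx]
        tissue = tissues[k % 3]
        dmr_rows.append({
            "dmr_id": f"dmr_{k:05d}", "chrom": c, "start": ws, "end": ws + 500,
            "tissue": tissue, "block": bi,
            "criterion": 2 if rng.random() < config.intermediate_fraction else 1,
            "ec_mouse": bool(rng.random() < config.p_ec_mouse),
            "ec_human": bool(rng.random() < config.p_ec_human),
        })
    unmeth = [eligible[idx][:2] for idx in pick[n_dmr_total:]]

    dmrs_by_contig: dict[str, list[dict]] = {c: [] for c in contigs}
    for row in dmr_rows:
        dmrs_by_contig[row["chrom"]].append(row)

    # -- block retention and rearrangement ----------------------------------
    # A block is kept in BOTH other species with probability
    # p_ortholog_retained; otherwise it is deleted from one of them.
    retained: dict[str, dict[str, np.ndarray]] = {}
    for c in contigs:
        nb = len(blocks[c])
        keep_both = rng.random(nb) < config.p_ortholog_retained
        drop_mouse = rng.random(nb) < 0.5
        retained[c] = {
            "mouse": keep_both | ~drop_mouse,
            "human": keep_both | drop_mouse,
        }
    rearranged: dict[str, set[int]] = {c: set() for c in contigs}
    if config.n_rearranged_blocks > 0:
        cands = [(r["chrom"], r["block"]) for r in dmr_rows]
        seen = sorted(set(cands))
        take = min(config.n_rearranged_blocks, len(seen))
        for i in rng.choice(len(seen), size=take, replace=False):
            c, bi = seen[i]
            rearranged[c].add(bi)
            retained[c]["mouse"][bi] = True   # force co-retention so the
            retained[c]["human"][bi] = True   # inconsistency is observable

    # -- species coordinate maps and chains ---------------------------------
    # block_q[c][sp][bi] = start of block bi's image in species sp, or -1
    block_q: dict[str, dict[str, np.ndarray]] = {}
    sp_sizes: dict[str, dict[str, int]] = {"mouse": {}, "human": {}}
    decoys: dict[str, list[tuple[int, int, int]]] = {c: [] for c in contigs}
    for c in contigs:
        block_q[c] = {}
        for sp in ("mouse", "human"):
            q = _geom(rng, config.gap_mean_length)
            qs = np.full(len(blocks[c]), -1, dtype=np.int64)
            for bi, (bs, blen) in enumerate(blocks[c]):
                q += _geom(rng, config.gap_mean_length)
                if retained[c][sp][bi]:
                    qs[bi] = q
                    q += blen
            block_q[c][sp] = qs
            size = q + 1000
            if sp == "human":
                # reserve a decoy zone hosting rearranged-block images
                for bi in sorted(rearranged[c]):
                    blen = blocks[c][bi][1]
                    decoys[c].append((bi, size, size + blen))
                    size += blen + 500
            sp_sizes[sp][c] = size

    chain_id = 0
    rat_sizes = {c: L for c in contigs}
    pair_chains: dict[str, list[Chain]] = {
        "rat_to_mouse": [], "rat_to_human": [], "mouse_to_human": []
    }
    for c in contigs:
        for sp, pair in (("mouse", "rat_to_mouse"), ("human", "rat_to_human")):
            pairs = [
                (bs, int(block_q[c][sp][bi]), blen)
                for bi, (bs, blen) in enumerate(blocks[c])
                if retained[c][sp][bi]
            ]
            if pairs:
                chain_id += 1
                pair_chains[pair].append(_chain_from_pairs(
                    pairs, c, L, c, sp_sizes[sp][c], 1e9, chain_id))
        mh_pairs = [
            (int(block_q[c]["mouse"][bi]), int(block_q[c]["human"][bi]), blen)
            for bi, (bs, blen) in enumerate(blocks[c])
            if retained[c]["mouse"][bi] and retained[c]["human"][bi]
            and bi not in rearranged[c]
        ]
        if mh_pairs:
            chain_id += 1
            pair_chains["mouse_to_human"].append(_chain_from_pairs(
                mh_pairs, c, sp_sizes["mouse"][c], c, sp_sizes["human"][c],
                1e9, chain_id))
        for bi, d_lo, d_hi in decoys[c]:
            chain_id += 1
            m_lo = int(block_q[c]["mouse"][bi])
            blen = blocks[c][bi][1]
            pair_chains["mouse_to_human"].append(_chain_from_pairs(
                [(m_lo, d_lo, blen)], c, sp_sizes["mouse"][c], c,
                sp_sizes["human"][c], 1e6, chain_id))

    # -- species sequences and CpG images ------------------------------------
    sp_seq: dict[str, dict[str, np.ndarray]] = {"mouse": {}, "human": {}}
    sp_cpg: dict[str, dict[str, np.ndarray]] = {"mouse": {}, "human": {}}
    # rat CpG index -> species CpG position (for level bookkeeping)
    cpg_image: dict[str, dict[str, np.ndarray]] = {"mouse": {}, "human": {}}
    for c in contigs:
        for sp in ("mouse", "human"):
            seq = _random_seq(rng, sp_sizes[sp][c])
            img = np.full(len(rat_cpg[c]), -1, dtype=np.int64)
            for bi, (bs, blen) in enumerate(blocks[c]):
                if not retained[c][sp][bi]:
                    continue
                q0 = int(block_q[c][sp][bi])
                src = rat_seq[c][bs:bs + blen]
                sub = rng.random(blen) < config.substitution_rate
                dst = src.copy()
                dst[sub] = (dst[sub] + rng.integers(1, 4, int(sub.sum()))) % 4
                seq[q0:q0 + blen] = dst
                lo = np.searchsorted(rat_cpg[c], bs)
                hi = np.searchsorted(rat_cpg[c], bs + blen - 1)
                for j in range(lo, hi):
                    p = rat_cpg[c][j]
                    qpos = q0 + (p - bs)
                    seq[qpos] = _IDX["C"]
                    seq[qpos + 1] = _IDX["G"]
                    img[j] = qpos
            sp_seq[sp][c] = seq
            cpg_image[sp][c] = img
            sp_cpg[sp][c] = img[img >= 0]

    # -- motif planting -------------------------------------------------------
    def _clear_offset(cpgs: np.ndarray, lo: int, hi: int, mlen: int,
                      occupied: list[tuple[int, int]]) -> int | None:
        for _ in range(60):
            off = int(rng.integers(lo, hi - mlen))
            if np.searchsorted(cpgs, off + mlen) - np.searchsorted(cpgs, off - 1) > 0:
                continue
            if any(o < off + mlen and off < e for o, e in occupied):
                continue
            return off
        return None

    for row in dmr_rows:
        c, ws = row["chrom"], row["start"]
        row["motif"] = ""
        row["event_mouse"] = ""
        row["event_human"] = ""
        p_m = config.p_motif_in_ec if row["ec_mouse"] else config.p_motif_in_enc
        if rng.random() >= p_m:
            continue
        name = motif_names[int(rng.integers(len(motif_names)))]
        model = motif_models[name]
        text = _realize_consensus(model.consensus)
        off = _clear_offset(rat_cpg[c], ws + 10, ws + 490, model.length, [])
        if off is None:
            continue
        _write_motif(rat_seq[c], off, text)
        row["motif"] = name
        row["motif_offset"] = off
        bs, blen = blocks[c][row["block"]]
        for sp in ("mouse", "human"):
            if not retained[c][sp][row["block"]]:
                continue
            q0 = int(block_q[c][sp][row["block"]])
            img_off = q0 + (off - bs)
            u = rng.random()
            if u < config.p_turnover_given_motif:
                event = "turnover"
            elif u < config.p_turnover_given_motif + config.p_loss_given_motif:
                event = "loss"
            else:
                event = "conserved"
            if event == "conserved":
                _write_motif(sp_seq[sp][c], img_off, text)
            else:
                broken = _breaking_base(model.consensus[0], text[0]) + text[1:]
                _write_motif(sp_seq[sp][c], img_off, broken)
                if event == "turnover":
                    o_lo = q0 + (ws - bs)
                    sp_cpgs = np.sort(sp_cpg[sp][c])
                    new_off = _clear_offset(
                        sp_cpgs, o_lo + 10, o_lo + 490, model.length,
                        [(img_off, img_off + model.length)])
                    if new_off is None:
                        event = "loss"
                    else:
                        _write_motif(sp_seq[sp][c], new_off, text)
            row[f"event_{sp}"] = event

    # background motif instances (rat only, fates unmanaged)
    dmr_keys = {(r["chrom"], r["start"]) for r in dmr_rows}
    for c, ws, bi in eligible:
        if (c, ws) in dmr_keys:
            continue
        if rng.random() < config.p_motif_background:
            name = motif_names[int(rng.integers(len(motif_names)))]
            model = motif_models[name]
            off = _clear_offset(rat_cpg[c], ws + 10, ws + 490, model.length, [])
            if off is not None:
                _write_motif(rat_seq[c], off, _realize_consensus(model.consensus))

    # -- methylation levels ---------------------------------------------------
    def _levels(rng, n, mean):
        return np.clip(rng.normal(mean, config.level_sd, n), 0.001, 0.999)

    def _window_slice(cpgs, ws):
        return np.searchsorted(cpgs, ws), np.searchsorted(cpgs, ws + 500)

    rat_levels: dict[str, dict[str, np.ndarray]] = {}
    for c in contigs:
        n = len(rat_cpg[c])
        rat_levels[c] = {t: _levels(rng, n, config.hyper_mean) for t in tissues}
        for row in dmrs_by_contig[c]:
            lo, hi = _window_slice(rat_cpg[c], row["start"])
            mean = (config.intermediate_mean if row["criterion"] == 2
                    else config.hypo_mean)
            rat_levels[c][row["tissue"]][lo:hi] = _levels(rng, hi - lo, mean)
        for uc, ws in unmeth:
            if uc != c:
                continue
            lo, hi = _window_slice(rat_cpg[c], ws)
            for t in tissues:
                rat_levels[c][t][lo:hi] = _levels(rng, hi - lo, config.hypo_mean)

    sp_levels: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for sp in ("mouse", "human"):
        sp_levels[sp] = {}
        for c in contigs:
            n = len(rat_cpg[c])  # indexed by rat CpG; filtered at write time
            sp_levels[sp][c] = {t: _levels(rng, n, config.hyper_mean)
                                for t in tissues}
            for row in dmrs_by_contig[c]:
                if not retained[c][sp][row["block"]]:
                    continue
                if not row[f"ec_{sp}"]:
                    continue  # ENC orthologs stay methylated everywhere
                lo, hi = _window_slice(rat_cpg[c], row["start"])
                sp_levels[sp][c][row["tissue"]][lo:hi] = _levels(
                    rng, hi - lo, config.hypo_mean)
            for uc, ws in unmeth:
                if uc != c:
                    continue
                lo, hi = _window_slice(rat_cpg[c], ws)
                for t in tissues:
                    sp_levels[sp][c][t][lo:hi] = _levels(
                        rng, hi - lo, config.hypo_mean)

    # -- conserved elements (rat assembly), coupled to EC-in-mouse -----------
    element_rows: list[tuple[str, int, int]] = []
    for row in dmr_rows:
        rate = (config.element_overlap_rate_ec if row["ec_mouse"]
                else config.element_overlap_rate_enc)
        row["element"] = bool(rng.random() < rate)
        if row["element"]:
            element_rows.append((row["chrom"], row["start"] + 125,
                                 row["start"] + 375))
    for c in contigs:
        forb = np.array(sorted(r["start"] for r in dmrs_by_contig[c]),
                        dtype=np.int64)
        for s, e in _sample_clear(rng, L, config.n_background_elements,
                                  100, 300, forb, forb + 500):
            element_rows.append((c, s, e))

    # -- genes, CGIs, repeats -------------------------------------------------
    def _make_genes(rng, c, length, prefix):
        genes = []
        for gi in range(config.n_genes_per_contig):
            tx_len = int(rng.integers(5_000, 30_000))
            tx_start = int(rng.integers(2_500, max(2_501, length - tx_len - 2_500)))
            tx_end = tx_start + tx_len
            strand = "+" if rng.random() < 0.5 else "-"
            k = int(rng.integers(3, 7))
            pts = np.sort(rng.choice(
                np.arange(tx_start, tx_end - 500, 10), size=k, replace=False))
            starts, ends = [], []
            for j, s in enumerate(pts):
                lim = pts[j + 1] if j + 1 < k else tx_end
                e = min(int(s) + int(rng.integers(100, 400)), int(lim), tx_end)
                if e > s:
                    starts.append(int(s))
                    ends.append(e)
            cds_s = min(starts[0] + 50, tx_end - 1)
            cds_e = max(ends[-1] - 50, cds_s + 1)
            genes.append(GeneRecord(
                f"{prefix}_{c}_g{gi}", c, strand, tx_start, tx_end,
                cds_s, cds_e, tuple(starts), tuple(ends)))
        return genes

    genes_by_sp = {
        "rat": [g for c in contigs for g in _make_genes(rng, c, L, "rat")],
        "mouse": [g for c in contigs
                  for g in _make_genes(rng, c, sp_sizes["mouse"][c], "mouse")],
        "human": [g for c in contigs
                  for g in _make_genes(rng, c, sp_sizes["human"][c], "human")],
    }
    cgi_rows = []
    for g in genes_by_sp["rat"][::3]:
        lo = max(0, g.tss - 150)
        cgi_rows.append((g.chrom, lo, g.tss + 350))
    for uc, ws in unmeth:
        cgi_rows.append((uc, ws + 100, ws + 400))
    repeat_rows = []
    for c in contigs:
        for _ in range(300):
            s = int(rng.integers(0, L - 1_000))
            repeat_rows.append((c, s, s + int(rng.integers(150, 1_000))))

    # -- score wigs (mouse/human assemblies), coupled to EC status ------------
    score_tracks: dict[str, ScoreTrack] = {}
    for sp in ("mouse", "human"):
        tr = ScoreTrack()
        for c in contigs:
            vals = rng.normal(0.0, config.score_base_sd, sp_sizes[sp][c])
            for row in dmrs_by_contig[c]:
                if not retained[c][sp][row["block"]]:
                    continue
                bs, _ = blocks[c][row["block"]]
                q0 = int(block_q[c][sp][row["block"]])
                o_lo = q0 + (row["start"] - bs)
                shift = (config.score_coupling if row[f"ec_{sp}"] else 0.0)
                shift += rng.normal(0.0, config.score_region_sd)
                vals[o_lo:o_lo + 500] += shift
            tr.add_segment(c, 0, vals)
        score_tracks[sp] = tr

    # -- histone peaks ---------------------------------------------------------
    peak_files: dict[tuple[str, str], list[tuple[str, int, int, int]]] = {}
    for sp in ("mouse", "human"):
        ortho_by_contig: dict[str, list[int]] = {c: [] for c in contigs}
        for row in dmr_rows:
            c = row["chrom"]
            if retained[c][sp][row["block"]]:
                bs, _ = blocks[c][row["block"]]
                q0 = int(block_q[c][sp][row["block"]])
                ortho_by_contig[c].append(q0 + (row["start"] - bs))
        for t in tissues:
            rows: list[tuple[str, int, int, int]] = []
            for row in dmr_rows:
                if row["tissue"] != t:
                    row.setdefault(f"peak_{sp}", False)
                    continue
                c = row["chrom"]
                planted = False
                if retained[c][sp][row["block"]]:
                    rate = (config.peak_rate_ec if row[f"ec_{sp}"]
                            else config.peak_rate_enc)
                    if rng.random() < rate:
                        bs, _ = blocks[c][row["block"]]
                        q0 = int(block_q[c][sp][row["block"]])
                        o_lo = q0 + (row["start"] - bs)
                        lo = max(0, o_lo - 200)
                        rows.append((c, lo, o_lo + 700, (o_lo + 250) - lo))
                        planted = True
                row[f"peak_{sp}"] = row.get(f"peak_{sp}", False) or planted
            for c in contigs:
                forb = np.array(sorted(ortho_by_contig[c]), dtype=np.int64)
                for s, e in _sample_clear(
                        rng, sp_sizes[sp][c], config.n_background_peaks,
                        400, 900, forb, forb + 500):
                    rows.append((c, s, e, (e - s) // 2))
            peak_files[(sp, t)] = rows

    # -- write everything ------------------------------------------------------
    from .methylome import MethylomeTrack

    _write_fasta(out / "rat" / "genome.fa", rat_seq)
    write_chrom_sizes(rat_sizes, out / "rat" / "chrom.sizes")
    for sp in ("mouse", "human"):
        _write_fasta(out / sp / "genome.fa", sp_seq[sp])
        write_chrom_sizes(sp_sizes[sp], out / sp / "chrom.sizes")
        write_fixedstep_wig(score_tracks[sp], out / sp / "scores.wig",
                            precision=2)
        write_genepred(genes_by_sp[sp], out / sp / "genes.genepred")
        for t in tissues:
            with open(out / sp / f"peaks_{t}.bed", "w") as fh:
                for i, (c, s, e, so) in enumerate(peak_files[(sp, t)]):
                    fh.write(f"{c}\t{s}\t{e}\tpeak_{i}\t0\t.\t0\t-1\t-1\t{so}\n")
    write_genepred(genes_by_sp["rat"], out / "rat" / "genes.genepred")
    write_bed(IntervalSet([GenomicInterval(c, s, e) for c, s, e in cgi_rows]),
              out / "rat" / "cgi.bed")
    write_bed(IntervalSet([GenomicInterval(c, s, e) for c, s, e in repeat_rows]),
              out / "rat" / "repeats.bed")
    element_rows.sort()
    write_bed(IntervalSet([GenomicInterval(c, s, e) for c, s, e in element_rows]),
              out / "rat" / "conserved_elements.bed")

    for t in tissues:
        sites = [(c, int(p), float(l))
                 for c in contigs
                 for p, l in zip(rat_cpg[c], rat_levels[c][t])]
        MethylomeTrack.from_sites(sites, "rat", t).to_bedgraph(
            out / "rat" / f"meth_{t}.bedgraph")
        for sp in ("mouse", "human"):
            sites = []
            for c in contigs:
                img = cpg_image[sp][c]
                keep = img >= 0
                for p, l in zip(img[keep], sp_levels[sp][c][t][keep]):
                    sites.append((c, int(p), float(l)))
            MethylomeTrack.from_sites(sites, sp, t).to_bedgraph(
                out / sp / f"meth_{t}.bedgraph")

    for pair, chains in pair_chains.items():
        write_chain(chains, out / "chains" / f"{pair}.chain")

    with open(out / "rat" / "qvalues.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tqvalue\n")
        for row in sorted(dmr_rows, key=lambda r: (r["chrom"], r["start"])):
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                     f"{config.q_planted:g}\n")

    truth_cols = [
        "dmr_id", "chrom", "start", "end", "tissue", "criterion",
        "ec_mouse", "ec_human", "element", "motif",
        "event_mouse", "event_human", "peak_mouse", "peak_human",
    ]
    records = []
    for row in dmr_rows:
        c = row["chrom"]
        rec = {k: row.get(k, "") for k in truth_cols}
        for sp in ("mouse", "human"):
            if retained[c][sp][row["block"]]:
                bs, _ = blocks[c][row["block"]]
                q0 = int(block_q[c][sp][row["block"]])
                rec[f"{sp}_start"] = q0 + (row["start"] - bs)
            else:
                rec[f"{sp}_start"] = -1
        rec["rearranged"] = row["block"] in rearranged[c]
        records.append(rec)
    pd.DataFrame(records).to_csv(out / "truth.tsv", sep="\t", index=False)
    config.to_yaml(out / "config.yaml")
    return TrioBundle(out)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def recovery_report(result, bundle: TrioBundle) -> dict:
    """Score pipeline outputs against the bundle's planted truth.

    ``result`` is a :class:`epicons.pipeline.PipelineResult`.  Returns a flat
    dict of metrics: tsDMR precision/recall, per-pair estimated vs planted EC
    fraction, turnover confusion summary, the genetic-conservation EC-vs-ENC
    chi-square, the three-way recovery rate, and the score-bin trend.
    """
    from scipy.stats import spearmanr

    from .conservation import EC, ENC
    from .enrichment import chi2_2x2

    truth = bundle.truth()
    cfg = bundle.config
    report: dict[str, float] = {}

    planted = {(r.chrom, r.start, r.tissue) for r in truth.itertuples()}
    called = {
        (d.interval.chrom, d.interval.start, tissue)
        for tissue, dmrs in result.calls.items()
        for d in dmrs
    }
    tp = len(planted & called)
    report["tsdmr_recall"] = tp / len(planted) if planted else float("nan")
    report["tsdmr_precision"] = tp / len(called) if called else float("nan")

    for sp, p_ec in (("mouse", cfg.p_ec_mouse), ("human", cfg.p_ec_human)):
        pair = f"rat_to_{sp}"
        calls = result.conservation.get(pair, [])
        n_ec = sum(1 for c in calls if c.status == EC)
        n_enc = sum(1 for c in calls if c.status == ENC)
        est = n_ec / (n_ec + n_enc) if (n_ec + n_enc) else float("nan")
        report[f"ec_fraction_{sp}"] = est
        report[f"ec_fraction_error_{sp}"] = abs(est - p_ec)

    # turnover confusion over planted motif events
    label_map = {"conserved": "CONSERVED_IN_PLACE", "turnover": "TURNOVER",
                 "loss": "LOSS"}
    pred_by_key = {
        (r["dmr_key"], r["species"], r["motif"]): r["call"]
        for r in result.turnover
    }
    confusion: dict[tuple[str, str], int] = {}
    for r in truth.itertuples():
        if not isinstance(r.motif, str) or not r.motif:
            continue
        for sp in ("mouse", "human"):
            event = getattr(r, f"event_{sp}")
            if event not in label_map:
                continue
            key = ((r.chrom, r.start, r.tissue), sp, r.motif)
            pred = pred_by_key.get(key)
            if pred is None:
                continue
            confusion[(label_map[event], pred)] = \
                confusion.get((label_map[event], pred), 0) + 1
    labels = sorted({k[0] for k in confusion} | {k[1] for k in confusion})
    precisions, recalls = [], []
    for lab in labels:
        tp_l = confusion.get((lab, lab), 0)
        pred_n = sum(v for (t, p), v in confusion.items() if p == lab)
        true_n = sum(v for (t, p), v in confusion.items() if t == lab)
        if pred_n:
            precisions.append(tp_l / pred_n)
        if true_n:
            recalls.append(tp_l / true_n)
    report["turnover_precision"] = float(np.mean(precisions)) if precisions else float("nan")
    report["turnover_recall"] = float(np.mean(recalls)) if recalls else float("nan")
    report["turnover_n"] = float(sum(confusion.values()))

    # genetic-conservation contrast (rat-mouse EC vs ENC)
    calls = result.conservation.get("rat_to_mouse", [])
    table = np.zeros((2, 2), dtype=int)
    for c in calls:
        if c.status not in (EC, ENC):
            continue
        key = (c.dmr.interval.chrom, c.dmr.interval.start)
        gcall = result.genetic.get(key)
        if gcall is None:
            continue
        i = 0 if c.status == EC else 1
        j = 0 if gcall.conserved else 1
        table[i, j] += 1
    stat, p = chi2_2x2(table)
    report["genetic_contrast_chi2"] = stat
    report["genetic_contrast_p"] = p
    ec_row, enc_row = table[0], table[1]
    report["genetic_rate_ec"] = ec_row[0] / ec_row.sum() if ec_row.sum() else float("nan")
    report["genetic_rate_enc"] = enc_row[0] / enc_row.sum() if enc_row.sum() else float("nan")

    # three-way recovery vs the retention parameter
    three_keys = {(o.rat.chrom, o.rat.start) for o in result.threeway}
    dmr_keys = [(d.interval.chrom, d.interval.start)
                for dmrs in result.calls.values() for d in dmrs]
    if dmr_keys:
        frac3 = sum(1 for k in dmr_keys if k in three_keys) / len(dmr_keys)
        report["threeway_fraction"] = frac3
        report["threeway_fraction_error"] = abs(frac3 - cfg.p_ortholog_retained)

    if result.curve is not None:
        rho, _ = spearmanr(result.curve["bin"], result.curve["ec_fraction"])
        report["phylop_trend_spearman"] = float(rho)
    return report
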