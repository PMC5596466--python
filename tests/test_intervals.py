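"""Coordinate core: BED/chain/wig/genePred I/O and interval arithmetic."""

import numpy as np
import pytest

from epicons.intervals import (
    FormatError,
    GenomicInterval,
    IntervalSet,
    ScoreTrack,
    overlap_bases,
    parse_bed,
    parse_chain,
    parse_genepred,
    parse_wig,
    tile_genome,
    write_bed,
    write_chain,
    write_fixedstep_wig,
    write_genepred,
)
from epicons.intervals import GeneRecord

from conftest import random_chain


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chrA", 10, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chrA", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)
        assert len(GenomicInterval("chrA", 0, 500)) == 500

    def test_overlap(self):
        a = GenomicInterval("chrA", 100, 200)
        assert a.overlap(GenomicInterval("chrA", 150, 300)) == 50
        assert a.overlap(GenomicInterval("chrB", 150, 300)) == 0
        assert a.overlap(GenomicInterval("chrA", 200, 300)) == 0


class TestBed:
    def test_basic(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("# comment\ntrack name=x\nchrA\t0\t500\n")
        iset = parse_bed(p)
        assert len(iset) == 1
        assert iset[0] == GenomicInterval("chrA", 0, 500)

    def test_invalid_interval_names_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrA\t0\t500\nchrA\t10\t5\n")
        with pytest.raises(FormatError, match=":2"):
            parse_bed(p)

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(1)
        iset = IntervalSet(name="rt")
        for i in range(100):
            s = int(rng.integers(0, 10_000))
            iv = GenomicInterval(f"chr{rng.integers(1, 4)}", s,
                                 s + int(rng.integers(1, 500)))
            iset.append(iv, (f"name{i}", str(int(rng.integers(0, 1000)))))
        p = tmp_path / "rt.bed"
        write_bed(iset, p)
        back = parse_bed(p)
        assert back.intervals == iset.intervals
        assert back.extras == iset.extras


class TestOverlapBasesHypothesis:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    interval_lists = st.lists(
        st.tuples(st.integers(0, 2_000), st.integers(1, 300)),
        min_size=0, max_size=12,
    )

    @given(interval_lists, st.integers(0, 2_000), st.integers(1, 500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_overlap_counts_each_base_once(self, raw, a_start, a_len):
        ivs = [GenomicInterval("chrA", s, s + l) for s, l in raw]
        a = GenomicInterval("chrA", a_start, a_start + a_len)
        got = overlap_bases(a, IntervalSet(ivs))
        covered = set()
        for iv in ivs:
            covered.update(range(iv.start, iv.end))
        assert got == len(covered & set(range(a.start, a.end)))
        assert 0 <= got <= len(a)


class TestOverlapBases:
    def test_examples(self):
        a = GenomicInterval("chrA", 0, 500)
        assert overlap_bases(a, IntervalSet([GenomicInterval("chrA", 100, 200)])) == 100
        s = IntervalSet([GenomicInterval("chrA", 400, 600),
                         GenomicInterval("chrA", 450, 700)])
        assert overlap_bases(a, s) == 100  # merged [400,700) ∩ [0,500)
        assert overlap_bases(a, IntervalSet()) == 0

    def test_matches_per_base_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            ivs = []
            for _ in range(rng.integers(1, 15)):
                s = int(rng.integers(0, 5_000))
                ivs.append(GenomicInterval("chrA", s, s + int(rng.integers(1, 800))))
            iset = IntervalSet(ivs)
            a = GenomicInterval("chrA", int(rng.integers(0, 4_000)),
                                int(rng.integers(4_000, 6_000)))
            covered = set()
            for iv in ivs:
                covered.update(range(iv.start, iv.end))
            expected = sum(1 for p in range(a.start, a.end) if p in covered)
            assert overlap_bases(a, iset) == expected


class TestTileGenome:
    def test_counts(self):
        assert len(tile_genome({"c": 1500}, 500)) == 3
        assert len(tile_genome({"c": 1499}, 500)) == 2

    def test_coverage_bounds(self):
        rng = np.random.default_rng(3)
        sizes = {f"c{i}": int(rng.integers(600, 20_000)) for i in range(5)}
        tiles = tile_genome(sizes, 500)
        total = len(tiles) * 500
        genome = sum(sizes.values())
        assert total <= genome
        assert total >= genome - len(sizes) * 499


class TestChain:
    def test_identity_chain(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 1000 chrA 1000 + 0 100 chrB 1000 + 0 100 1\n100\n")
        (c,) = parse_chain(p)
        assert c.t_span == 100
        assert len(c.blocks) == 1 and c.blocks[0].size == 100

    def test_block_sum_arithmetic(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 5 chrA 1000 + 0 100 chrB 1000 + 0 90 2\n40 10 0\n50\n")
        (c,) = parse_chain(p)
        assert c.t_span == 100
        assert c.q_span == 90

    def test_inconsistent_sums_rejected(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 5 chrA 1000 + 0 120 chrB 1000 + 0 90 7\n40 10 0\n50\n")
        with pytest.raises(FormatError, match="chain 7"):
            parse_chain(p)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        chains = [random_chain(rng, i + 1) for i in range(25)]
        p = tmp_path / "rt.chain"
        write_chain(chains, p)
        back = parse_chain(p)
        assert len(back) == len(chains)
        for a, b in zip(chains, back):
            assert (a.id, a.score, a.t_name, a.t_start, a.t_end,
                    a.q_name, a.q_strand, a.q_start, a.q_end) == \
                   (b.id, b.score, b.t_name, b.t_start, b.t_end,
                    b.q_name, b.q_strand, b.q_start, b.q_end)
            assert a.blocks == b.blocks


class TestWig:
    def test_fixed_step(self, tmp_path):
        p = tmp_path / "a.wig"
        p.write_text("fixedStep chrom=chrA start=11 step=1\n1.0\n2.0\n3.0\n")
        track = parse_wig(p)
        iv = GenomicInterval("chrA", 10, 13)
        assert list(track.values(iv)) == [1.0, 2.0, 3.0]
        assert track.mean(iv) == 2.0
        assert np.isnan(track.mean(GenomicInterval("chrA", 100, 110)))

    def test_variable_step_and_span(self, tmp_path):
        p = tmp_path / "a.wig"
        p.write_text("variableStep chrom=chrA span=2\n5\t1.5\n11\t2.5\n")
        track = parse_wig(p)
        v = track.values(GenomicInterval("chrA", 4, 12), fill=0.0)
        assert list(v) == [1.5, 1.5, 0, 0, 0, 0, 2.5, 2.5]

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        track = ScoreTrack()
        track.add_segment("chrA", 100, rng.normal(size=50))
        track.add_segment("chrB", 0, rng.normal(size=30))
        p = tmp_path / "rt.wig"
        write_fixedstep_wig(track, p, precision=6)
        back = parse_wig(p)
        for chrom in ("chrA", "chrB"):
            for (s1, v1), (s2, v2) in zip(track.segments(chrom), back.segments(chrom)):
                assert s1 == s2
                assert np.allclose(v1, v2, atol=1e-6)


class TestGenePred:
    def test_round_trip_and_tss(self, tmp_path):
        genes = [
            GeneRecord("g1", "chrA", "+", 1000, 5000, 1200, 4800,
                       (1000, 3000), (1500, 5000)),
            GeneRecord("g2", "chrA", "-", 500, 900),
        ]
        p = tmp_path / "g.gp"
        write_genepred(genes, p)
        back = parse_genepred(p)
        assert back[0].name == "g1" and back[0].tss == 1000
        assert back[1].tss == 900  # '-' strand: TSS at txEnd
        assert back[0].exon_starts == (1000, 3000)

    def test_invalid_exon_rejected(self, tmp_path):
        p = tmp_path / "g.gp"
        p.write_text("g\tchrA\t+\t100\t200\t100\t200\t1\t50,\t150,\n")
        with pytest.raises(FormatError):
            parse_genepred(p)
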