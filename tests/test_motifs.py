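"""Motif scanning, GC-matched backgrounds, enrichment, and turnover calls."""

import numpy as np
import pytest

from epicons.intervals import Chain, ChainBlock, GenomicInterval
from epicons.motifs import (
    ABSENT_BOTH,
    CONSERVED_IN_PLACE,
    GAIN,
    IUPAC,
    LOSS,
    TURNOVER,
    MotifModel,
    classify_turnover,
    enrichment_by_ec,
    gc_fraction,
    gc_matched_background,
    reverse_complement,
    scan,
    scan_region,
)

ERG = MotifModel("Erg", consensus="ACAGGAAGTG")
FLI1 = MotifModel("Fli1", consensus="TCAGGAAGCC")
LHX3 = MotifModel("Lhx3", consensus="CTAATTAATT")


class TestConsensusScan:
    def test_erg_worked_example(self):
        hits = scan("TTACAGGAAGTGTT", ERG)
        assert len(hits) == 1
        assert hits[0].interval.start == 2 and hits[0].strand == "+"

    def test_substitution_destroys_motif(self):
        # A->G at the first consensus position abolishes the Erg site
        assert scan("TTGCAGGAAGTGTT", ERG) == []
        # G->A mismatch destroys the Fli1 site
        assert len(scan("AATCAGGAAGCCAA", FLI1)) == 1
        assert scan("AATCAAGAAGCCAA", FLI1) == []

    def test_lhx3_core_motif(self):
        assert len(scan("GGGCTAATTAATTGGG", LHX3)) == 1

    def test_reverse_strand_hit(self):
        seq = "TT" + reverse_complement("ACAGGAAGTG") + "TT"
        hits = scan(seq, ERG)
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_strand_symmetry(self):
        rng = np.random.default_rng(71)
        letters = "ACGT"
        codes = list(IUPAC)
        for _ in range(30):
            seq = "".join(rng.choice(list(letters + "N"), size=200))
            motif = MotifModel(
                "m", consensus="".join(rng.choice(codes, size=6)))
            fwd = scan(seq, motif)
            rev = scan(reverse_complement(seq), motif)
            assert len(fwd) == len(rev)
            assert sorted(h.strand for h in fwd) == \
                sorted({"+": "-", "-": "+"}[h.strand] for h in rev)

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(72)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGTN"), size=300,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            motif = MotifModel(
                "m", consensus="".join(rng.choice(list(IUPAC), size=4)))
            expected = set()
            for off in range(len(seq) - motif.length + 1):
                word = seq[off:off + motif.length]
                if all(b in IUPAC[c] for b, c in zip(word, motif.consensus)):
                    expected.add((off, "+"))
                rc = reverse_complement(motif.consensus)
                if all(b in IUPAC[c] for b, c in zip(word, rc)):
                    expected.add((off, "-"))
            got = {(h.interval.start, h.strand) for h in scan(seq, motif)}
            assert got == expected

    def test_motif_longer_than_sequence(self):
        assert scan("ACG", ERG) == []

    def test_genomic_coordinates(self):
        region = GenomicInterval("chr5", 1_000, 1_014)
        hits = scan_region("TTACAGGAAGTGTT", ERG, region)
        assert hits[0].interval == GenomicInterval("chr5", 1_002, 1_012, "+")


class TestPwmScan:
    def test_one_hot_pwm_equals_consensus(self):
        pwm = np.zeros((10, 4))
        for i, c in enumerate("ACAGGAAGTG"):
            pwm[i, "ACGT".index(c)] = 1.0
        model = MotifModel("ErgPwm", pwm=pwm)
        seq = "TTACAGGAAGTGTT"
        got = {(h.interval.start, h.strand) for h in scan(seq, model)}
        exp = {(h.interval.start, h.strand) for h in scan(seq, ERG)}
        assert got == exp

    def test_threshold_admits_degenerate_matches(self):
        pwm = np.full((4, 4), 0.1)
        pwm[:, 0] = 0.7  # prefers AAAA but tolerates one mismatch
        model = MotifModel("soft", pwm=pwm, threshold=2.0)
        hits = scan("AAAA", model, both_strands=False)
        assert len(hits) == 1
        assert scan("AACA", model, both_strands=False)  # still above 2.0

    def test_pwm_validation(self):
        with pytest.raises(ValueError):
            MotifModel("bad", pwm=np.ones((4, 4)))


class TestGcMatchedBackground:
    def _genome(self, windows):
        seq = {}
        for iv, gc in windows:
            n_gc = int(round(gc * len(iv)))
            s = "G" * n_gc + "A" * (len(iv) - n_gc)
            seq.setdefault(iv.chrom, ["A"] * 1_000_000)
            seq[iv.chrom][iv.start:iv.end] = list(s)
        return {c: "".join(v) for c, v in seq.items()}

    def test_histogram_matched_exactly(self):
        rng = np.random.default_rng(73)
        windows = []
        for i in range(300):
            iv = GenomicInterval("chrA", i * 1_000, i * 1_000 + 500)
            windows.append((iv, float(rng.choice([0.3, 0.5, 0.7]))))
        genome = self._genome(windows)
        targets = [iv for iv, _ in windows[:40]]
        universe = [iv for iv, _ in windows[40:]]
        bg1 = gc_matched_background(targets, universe, genome, seed=1)
        bg2 = gc_matched_background(targets, universe, genome, seed=2)

        def hist(ivs):
            from collections import Counter

            return Counter(int(gc_fraction(genome["chrA"][iv.start:iv.end]) // 0.05)
                           for iv in ivs)

        assert hist(bg1) == hist(targets)
        assert hist(bg2) == hist(targets)
        assert bg1.intervals != bg2.intervals

    def test_empty_bin_names_range(self):
        windows = [(GenomicInterval("chrA", i * 1_000, i * 1_000 + 500), 0.5)
                   for i in range(10)]
        genome = self._genome(windows)
        target = [GenomicInterval("chrA", 500_000, 500_500)]  # all-A: GC 0
        with pytest.raises(ValueError, match=r"GC bin \[0\.00"):
            gc_matched_background(target, [iv for iv, _ in windows], genome,
                                  seed=1)


class TestEnrichmentByEc:
    def _setup(self, rng, p_ec_hit=0.8, p_enc_hit=0.1, p_bg_hit=0.1, n=150):
        genome = {"chrA": "".join(rng.choice(list("AT"), size=(3 * n) * 600))}
        arr = list(genome["chrA"])
        regions, background = [], []
        for i in range(2 * n):
            iv = GenomicInterval("chrA", i * 600, i * 600 + 500)
            status = "EC" if i < n else "ENC"
            p = p_ec_hit if status == "EC" else p_enc_hit
            if rng.random() < p:
                arr[iv.start + 100:iv.start + 110] = list("ACAGGAAGTG")
            regions.append((iv, status))
        for i in range(2 * n, 3 * n):
            iv = GenomicInterval("chrA", i * 600, i * 600 + 500)
            if rng.random() < p_bg_hit:
                arr[iv.start + 100:iv.start + 110] = list("ACAGGAAGTG")
            background.append(iv)
        genome["chrA"] = "".join(arr)
        return regions, background, genome

    def test_planted_contrast(self):
        rng = np.random.default_rng(74)
        regions, background, genome = self._setup(rng)
        df = enrichment_by_ec(regions, background, [ERG], genome)
        by = df.set_index("stratum")
        assert by.loc["EC", "fold"] > 4
        assert 0.4 < by.loc["ENC", "fold"] < 2.5
        assert by.loc["EC", "p_value"] < 1e-6

    def test_background_equals_targets_gives_fold_one(self):
        rng = np.random.default_rng(75)
        regions, _, genome = self._setup(rng)
        ivs = [iv for iv, _ in regions]
        df = enrichment_by_ec(regions, ivs, [ERG], genome)
        assert df.set_index("stratum").loc["all", "fold"] == pytest.approx(1.0)

    def test_absent_motif_reported_undefined(self):
        rng = np.random.default_rng(76)
        regions, background, genome = self._setup(rng, 0, 0, 0)
        df = enrichment_by_ec(regions, background, [ERG], genome)
        assert df["fold"].isna().all()


def identity_chain(length=10_000):
    return Chain(id=1, score=1e6, t_name="chrA", t_size=length, t_start=0,
                 t_end=length, q_name="chrA", q_size=length, q_strand="+",
                 q_start=0, q_end=length, blocks=[ChainBlock(length)])


class TestClassifyTurnover:
    SRC = GenomicInterval("chrA", 1_000, 1_500)
    DST = GenomicInterval("chrA", 1_000, 1_500)

    def _hits(self, *starts):
        return [
            type("H", (), {"interval": GenomicInterval("chrA", s, s + 10)})()
            for s in starts
        ]

    def test_all_classes(self):
        chains = [identity_chain()]
        assert classify_turnover(self.SRC, self._hits(1_100), self.DST,
                                 self._hits(1_100), chains) == CONSERVED_IN_PLACE
        # dst hit 84 bp away from the destroyed source site: turnover
        assert classify_turnover(self.SRC, self._hits(1_200), self.DST,
                                 self._hits(1_116), chains) == TURNOVER
        assert classify_turnover(self.SRC, self._hits(1_200), self.DST,
                                 [], chains) == LOSS
        assert classify_turnover(self.SRC, [], self.DST,
                                 self._hits(1_116), chains) == GAIN
        assert classify_turnover(self.SRC, [], self.DST, [], chains) == ABSENT_BOTH

    def test_swap_symmetry(self):
        chains = [identity_chain()]
        cases = [
            (self._hits(1_100), self._hits(1_100)),
            (self._hits(1_200), self._hits(1_116)),
            (self._hits(1_200), []),
            ([], self._hits(1_116)),
            ([], []),
        ]
        swap = {LOSS: GAIN, GAIN: LOSS}
        for src_hits, dst_hits in cases:
            fwd = classify_turnover(self.SRC, src_hits, self.DST, dst_hits, chains)
            rev = classify_turnover(self.DST, dst_hits, self.SRC, src_hits, chains)
            assert rev == swap.get(fwd, fwd)

    def test_non_ortholog_pair_rejected(self):
        chains = [identity_chain()]
        far = GenomicInterval("chrA", 8_000, 8_500)
        with pytest.raises(ValueError, match="ortholog"):
            classify_turnover(self.SRC, [], far, [], chains)
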