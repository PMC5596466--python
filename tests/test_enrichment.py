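"""Feature labelling, matched sampling, TSS distances, summit overlap,
profiles, and the shared statistical kernels."""

import numpy as np
import pytest

from epicons.enrichment import (
    AnnotationBundle,
    HistonePeak,
    assign_feature,
    bh_fdr,
    chi2_2x2,
    distance_enrichment,
    nearest_tss,
    parse_peaks,
    sample_matched,
    signal_profile,
    summit_overlap,
)
from epicons.intervals import GeneRecord, GenomicInterval, IntervalSet, ScoreTrack


def simple_gene(name="g", chrom="chrA", strand="+", tx=(10_000, 30_000),
                exons=((10_000, 10_500), (20_000, 20_500), (29_500, 30_000)),
                cds=(10_200, 29_800)):
    return GeneRecord(name, chrom, strand, tx[0], tx[1], cds[0], cds[1],
                      tuple(s for s, _ in exons), tuple(e for _, e in exons))


class TestAssignFeature:
    def test_intronic_window(self):
        bundle = AnnotationBundle([simple_gene()])
        assert assign_feature(GenomicInterval("chrA", 12_000, 12_500), bundle) \
            == "intron"

    def test_precedence_promoter_over_exon(self):
        # window covering 300 bp promoter and 200 bp exon: promoter wins
        gene = simple_gene(tx=(10_000, 30_000),
                           exons=((10_000, 11_000),), cds=(10_000, 30_000))
        bundle = AnnotationBundle([gene])
        win = GenomicInterval("chrA", 10_200, 10_700)  # promoter ends 10_500
        assert assign_feature(win, bundle) == "promoter"

    def test_intergenic_and_other(self):
        bundle = AnnotationBundle([simple_gene()])
        assert assign_feature(GenomicInterval("chrA", 50_000, 50_500), bundle) \
            == "intergenic"
        # half exon, half intron inside the gene: nothing exceeds 50%
        gene = simple_gene(exons=((10_000, 12_250),), cds=(10_000, 30_000))
        win = GenomicInterval("chrA", 12_000, 12_500)
        assert assign_feature(win, AnnotationBundle([gene])) == "other"

    def test_coverage_matches_brute_force(self):
        rng = np.random.default_rng(61)
        gene = simple_gene()
        cgi = IntervalSet([GenomicInterval("chrA", int(s), int(s) + 400)
                           for s in rng.integers(0, 40_000, size=8)])
        bundle = AnnotationBundle([gene], cgi=cgi)
        labels = bundle.label_sets()
        for _ in range(40):
            s = int(rng.integers(0, 45_000))
            win = GenomicInterval("chrA", s, s + 500)
            got = assign_feature(win, bundle)
            # brute-force winner under the same precedence
            expected = None
            for label in ("promoter", "CGI", "5utr", "exon", "3utr", "TE",
                          "intron"):
                iset = labels[label]
                covered = set()
                for iv in iset:
                    covered.update(range(iv.start, iv.end))
                cov = sum(1 for p in range(win.start, win.end) if p in covered)
                if cov > 250:
                    expected = label
                    break
            if expected is None:
                genic = set()
                for iv in labels["gene_span"]:
                    genic.update(range(iv.start, iv.end))
                out = sum(1 for p in range(win.start, win.end) if p not in genic)
                expected = "intergenic" if out > 250 else "other"
            assert got == expected


class TestSampleMatched:
    def _windows(self, label, n, offset=0):
        return [(GenomicInterval("chrA", offset + i * 500, offset + (i + 1) * 500),
                 label) for i in range(n)]

    def test_exact_composition_and_determinism(self):
        targets = self._windows("promoter", 5) + self._windows("intron", 10, 100_000)
        universe = self._windows("promoter", 50) + self._windows("intron", 80, 100_000)
        bg1 = sample_matched(targets, universe, seed=5)
        bg2 = sample_matched(targets, universe, seed=5)
        bg3 = sample_matched(targets, universe, seed=6)
        assert bg1.feature_composition == {"promoter": 5, "intron": 10}
        assert bg1.windows.intervals == bg2.windows.intervals
        assert bg3.feature_composition == bg1.feature_composition
        assert bg3.windows.intervals != bg1.windows.intervals

    def test_insufficient_stratum_names_label(self):
        targets = self._windows("exon", 5)
        universe = self._windows("exon", 3)
        with pytest.raises(ValueError, match="exon"):
            sample_matched(targets, universe, seed=1)
        bg = sample_matched(targets, universe, seed=1, replace=True)
        assert len(bg.windows) == 5

    def test_within_stratum_uniformity(self):
        # empirical inclusion frequency per window, chi-square GOF
        from scipy.stats import chisquare

        targets = self._windows("exon", 4)
        universe = self._windows("exon", 20)
        counts = np.zeros(20)
        n_rep = 3_000
        for seed in range(n_rep):
            bg = sample_matched(targets, universe, seed=seed)
            for iv in bg.windows:
                counts[iv.start // 500] += 1
        expected = np.full(20, counts.sum() / 20)
        _, p = chisquare(counts, expected)
        assert p > 0.001


class TestNearestTss:
    def test_examples(self):
        genes = [simple_gene(tx=(1_000, 5_000), exons=(), cds=(1_200, 4_800))]
        assert nearest_tss(GenomicInterval("chrA", 1_000, 1_500), genes) == 0
        minus = GeneRecord("m", "chrA", "-", 500, 900)
        assert nearest_tss(GenomicInterval("chrA", 1_000, 1_500), [minus]) == 100
        assert nearest_tss(GenomicInterval("chrZ", 0, 500), genes) is None

    def test_matches_all_pairs_minimum(self):
        rng = np.random.default_rng(62)
        genes = []
        for i in range(30):
            s = int(rng.integers(0, 500_000))
            genes.append(GeneRecord(f"g{i}", "chrA",
                                    "+" if rng.random() < 0.5 else "-",
                                    s, s + int(rng.integers(1_000, 20_000))))
        for _ in range(50):
            start = int(rng.integers(0, 500_000))
            region = GenomicInterval("chrA", start, start + 500)
            expected = min(abs(g.tss - start) for g in genes)
            assert nearest_tss(region, genes) == expected


class TestKernels:
    def test_chi2_closed_form(self):
        # [[30,70],[10,90]]: margins give expected [[20,80],[20,80]];
        # sum (O-E)^2/E = 5 + 1.25 + 5 + 1.25 = 12.5
        stat, p = chi2_2x2([[30, 70], [10, 90]])
        a, b, c, d = 30, 70, 10, 90
        n = a + b + c + d
        hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(12.5)
        assert stat == pytest.approx(hand)
        assert 0 < p < 1e-3

    def test_chi2_degenerate_margin(self):
        stat, p = chi2_2x2([[0, 0], [10, 90]])
        assert np.isnan(stat) and np.isnan(p)

    def test_bh_examples(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(63)
        p = rng.random(40)
        order = np.argsort(p)
        m = len(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_fdr(p), expected)
        assert (bh_fdr(p) >= p - 1e-12).all()


class TestDistanceEnrichment:
    def test_null_identity(self):
        rng = np.random.default_rng(64)
        d = rng.integers(0, 200_000, size=500).astype(float)
        df = distance_enrichment(d, d)
        present = df["fold"].notna()
        assert np.allclose(df.loc[present, "fold"], 1.0)
        assert (df.loc[present, "chi2_p"] > 0.999).all()

    def test_constructed_enrichment(self):
        rng = np.random.default_rng(65)
        targets = rng.integers(0, 1_000, size=200).astype(float)
        background = rng.integers(0, 200_000, size=2_000).astype(float)
        df = distance_enrichment(targets, background)
        first = df.iloc[0]
        assert first["fold"] > 1
        assert first["chi2_p"] < 0.05
        assert first["bh_q"] >= first["chi2_p"]


class TestSummitOverlap:
    def test_summit_containment_rule(self):
        region = GenomicInterval("chrA", 1_000, 1_500)
        at_start = HistonePeak(GenomicInterval("chrA", 800, 1_200), 1_000)
        outside = HistonePeak(GenomicInterval("chrA", 900, 1_100), 950)
        res = summit_overlap([region], [], [at_start])
        assert res["ec_overlap"] == 1  # summit at region start counts
        res = summit_overlap([region], [], [outside])
        assert res["ec_overlap"] == 0  # peak overlaps, summit does not

    def test_counts_match_enumeration(self):
        rng = np.random.default_rng(66)
        regions = [GenomicInterval("chrA", int(s), int(s) + 500)
                   for s in rng.integers(0, 100_000, size=60)]
        peaks = []
        for s in rng.integers(0, 100_000, size=40):
            s = int(s)
            peaks.append(HistonePeak(GenomicInterval("chrA", s, s + 800),
                                     s + int(rng.integers(0, 800))))
        res = summit_overlap(regions[:30], regions[30:], peaks)
        expect_ec = sum(
            1 for r in regions[:30]
            if any(r.start <= p.summit < r.end for p in peaks))
        expect_enc = sum(
            1 for r in regions[30:]
            if any(r.start <= p.summit < r.end for p in peaks))
        assert res["ec_overlap"] == expect_ec
        assert res["enc_overlap"] == expect_enc

    def test_parse_narrowpeak_summit(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chrA\t100\t600\tpeak_0\t0\t.\t5.0\t-1\t-1\t250\n")
        (peak,) = parse_peaks(p)
        assert peak.summit == 350


class TestSignalProfile:
    def test_constant_density(self):
        track = ScoreTrack()
        track.add_segment("chrA", 0, np.full(30_000, 2.5))
        regions = [GenomicInterval("chrA", 10_000, 10_500),
                   GenomicInterval("chrA", 14_000, 14_500)]
        offsets, means = signal_profile(regions, track)
        assert len(means) == 200
        assert offsets[0] == -5_000 and offsets[-1] == 4_950
        assert np.allclose(means, 2.5)

    def test_delta_at_midpoint(self):
        track = ScoreTrack()
        vals = np.zeros(30_000)
        vals[10_250] = 50.0  # midpoint of [10000,10500)
        track.add_segment("chrA", 0, vals)
        _, means = signal_profile([GenomicInterval("chrA", 10_000, 10_500)], track)
        assert np.count_nonzero(means) == 1
        assert means[100] > 0  # central bin starts at the midpoint

    def test_linearity_across_regions(self):
        rng = np.random.default_rng(67)
        track = ScoreTrack()
        track.add_segment("chrA", 0, rng.random(40_000))
        regions = [GenomicInterval("chrA", int(s), int(s) + 500)
                   for s in rng.integers(6_000, 30_000, size=8)]
        _, pooled = signal_profile(regions, track)
        singles = [signal_profile([r], track)[1] for r in regions]
        assert np.allclose(pooled, np.mean(singles, axis=0))
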