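# Methods

## Coordinates and formats

All coordinates are 0-based half-open (BED convention), including
genePred-style gene tables.  Chain files follow the UCSC format: the target
side is the source assembly, the target strand is always '+', and a
negative-strand query counts its coordinates from the reverse-complemented
query sequence.  Chains are normalized to forward-strand query coordinates at
parse time (original fields are kept so files round-trip), and every parsed
chain is checked against the block-sum invariants
`Σ size + Σ dt = tEnd − tStart` and `Σ size + Σ dq = qEnd − qStart`.
Wiggle `start` fields are 1-based and converted on input; step/span default
to 1.  Genome tiling uses fixed, left-aligned, non-overlapping windows and
drops a trailing remainder shorter than the window, so every emitted window
has exactly the nominal size (500 bp by default).

The TSS of a '-' strand transcript is reported at txEnd (the UCSC convention
for the transcript's 5' end), and promoters span 2 kb upstream plus 0.5 kb
downstream of the TSS on the transcribed strand.

## tsDMR calling

Window methylation is the arithmetic mean over the CpGs inside the window
(undefined for CpG-free windows; such windows are excluded because the rule
needs all three tissues).  Methylation status is categorical — unmethylated
(< 0.3), intermediate, methylated (> 0.7) — with the boundaries 0.3 and 0.7
classed intermediate because the defining inequalities are strict.  The two
calling criteria (hypo-vs-nonhypo; intermediate-vs-hyper) are mutually
exclusive and make per-tissue call sets provably disjoint: hypomethylation in
one tissue rules the window out for the other two.  Only hypomethylated
tsDMRs are called; hypermethylated ones are deliberately out of scope.  An
upstream differential-methylation q-value, when supplied per window, gates
calls at q < 1e-5; when absent the level criteria alone decide, keeping the
caller usable without the external DMR model that produces those q-values.

## Liftover

An interval maps through a single chain: among chains with **at least one
aligned base** inside the interval, the highest-scoring one wins (ties break
to the lowest chain id).  Requiring aligned-base overlap rather than mere
span overlap matters: an interval sitting in the gap of a dominant chain
falls through to a smaller chain covering it, which is how genuinely
rearranged segments acquire a (reconcilably wrong) image instead of silently
disappearing — mirroring UCSC liftOver's behaviour of mapping through
whichever chain actually aligns the bases.  The mapped image is the envelope
`[min, max)` of the per-base images on that chain; the mapping is accepted
when ≥ 50% of the source bases lie in aligned blocks and the envelope spans
≤ 1000 bp.  Both thresholds are parameters; the same values are reused for
50-bp subwindows in the score-bin analysis rather than inventing new ones.
Negative-strand images are reported in forward-strand coordinates with the
strand flagged.

Three-way orthologs: a source region mapped directly to species C and via
species B (lifting the B image with the same rules) is accepted when the two
C images overlap by ≥ 90% of the shorter image.  The min-length denominator
is symmetric and tolerant of small envelope differences; both images come
from the same acceptance rules so their lengths are comparable.

## Epigenetic conservation

For each tsDMR with a mapped ortholog, the ortholog's mean methylation is
computed per tissue in the other species; regions with zero CpGs in any
tissue track are set aside as NO_CPG (neither EC nor ENC), and unmapped
regions as NO_ORTHOLOG.  The EC rule on status triples is: target 0 with both
others in {1, 2}, or target 1 with both others 2.  Table percentages divide
EC counts by the full per-tissue tsDMR total (NO_ORTHOLOG/NO_CPG losses stay
in the denominator) and are rounded half-away-from-zero to integers, matching
how such tables are printed.

The enrichment test is exact hypergeometric: pooling a large random-region
background (classified by the same pipeline) with the tsDMRs into one urn —
population N = background + tsDMRs, successes K = background EC + observed
EC, draws n = tsDMRs — and taking the upper tail at the observed count.  The
urn construction is one of several defensible readings of "hypergeometric
test against a 40,000-region random sample"; this one makes the test exact
under that resampling scheme and is validated against Monte Carlo resampling
in the tests.

## Genetic conservation

A region is genetically conserved when ≥ 20% of its bases overlap the
(flattened) conserved-element set; the boundary is inclusive.  The score-bin
curve divides each 500-bp tsDMR into ten 50-bp subwindows, lifts each
subwindow, averages the per-base conservation score over the mapped image
(bases without score data are ignored; score-free subwindows are dropped),
sorts subwindows by mean score with genomic-order tie-breaking, and cuts them
into equal-sized bins (any remainder is distributed one-per-bin from the
lowest bins).  EC per subwindow is evaluated on the subwindow's own ortholog
by default; evaluating at the parent 500-bp window level is available via
`level="parent"` since the published description is ambiguous on this point.
Subwindows whose ortholog lacks CpGs in some tissue are excluded, consistent
with retaining only CpG-bearing orthologous regions elsewhere.

## Enrichment statistics

Feature labels require > 50% window coverage by the feature's flattened
intervals; when several qualify the fixed precedence promoter > CGI > 5'UTR >
exon > 3'UTR > TE > intron decides (the order is configurable; some order is
needed for determinism because these annotations overlap).  Windows mostly
outside transcript spans are intergenic; mostly-genic windows with no single
qualifying sub-feature are 'other'.  Matched backgrounds sample uniformly
without replacement within each feature stratum, reproducing the target
composition exactly and deterministically for a given seed.  TSS distances
are |TSS − window start| over genes on the window's contig.  Distance bins
default to 0–1, 1–2, 2–5, 5–10, 10–50, 50–100 and > 100 kb.  All 2×2 tests
are Pearson χ² without continuity correction (documented so the tests are
exact closed forms); multiple testing uses Benjamini–Hochberg step-up (via
statsmodels, checked against a hand-written oracle).  Histone-mark overlap
uses the summit-containment rule — a region overlaps a mark iff it contains a
peak summit, half-open — and signal profiles average per-bin mean density in
50-bp bins over ±5 kb around region midpoints, with data-free bases counted
as zero.

## Motifs

Consensus matching is exact under IUPAC classes (Hamming distance 0) on both
strands; 'N' in the sequence matches only an 'N' consensus position.  This
reflects how the turnover case analyses are reasoned about (single
substitutions "destroying" a site).  A PWM mode scores log-odds against a
uniform background with a default threshold of 80% of the maximum achievable
score, for users with matrix models; de novo discovery is out of scope — the
motif set is user-supplied.  Turnover classification lifts each source hit
(50% coverage rule on the 10-bp hit itself): an image sharing ≥ 1 base with a
destination hit is conserved in place; otherwise hits on both sides mean
turnover, source-only means loss, destination-only gain.  Swapping the two
regions maps loss ↔ gain and fixes the other classes.

## Synthetic trio generator

The generator emulates the statistical structure the analysis assumes, not
the biology of real genomes.  A reference ("rat") genome is partitioned into
conserved blocks (exponential lengths, mean 1.5 kb) separated by small gaps;
each block is retained in *both* other species with probability
`p_ortholog_retained` (default 0.9) and otherwise deleted from exactly one of
them, so the expected three-way recovery rate of planted regions equals the
parameter directly.  Retained blocks are copied with per-base substitutions
(5%) and flanked by geometric indels (mean 40 bp), which makes the three
chain files mutually consistent by construction; optional rearranged blocks
are excluded from the main mouse→human chain and mapped by a low-scoring
decoy chain to a reserved zone, so the composed path disagrees with the
direct path and three-way reconciliation rejects them.

CpG sites are planted at rate 0.02/bp on the reference and forced (as CG
dinucleotides) at their images in retained blocks, so orthologous regions
always carry CpGs.  Methylation levels are clipped normals around state means
(hypo 0.1, intermediate 0.5, hyper 0.85; sd 0.05), giving the bimodal global
distribution real methylomes show.  Per tissue, 300 windows fully inside
single blocks are planted as tsDMRs (10% criterion-2); planted EC flags
(mouse 0.3, human 0.15) decide whether the ortholog repeats the tissue
pattern or stays methylated.  Conserved elements cover planted regions at
0.6 (EC) vs 0.2 (ENC); peak summits fall in orthologs at the same pair of
rates; motif instances appear in 0.8 of EC vs 0.1 of ENC regions and, per
species, are conserved in place, turned over (site destroyed, new site
planted nearby), or lost.  The per-base score track is N(0, 0.3) plus a
per-region shift of `score_coupling` (1.5) for EC orthologs **plus a
per-region N(0, 0.75) jitter**; the jitter makes the EC-probability-vs-score
relation smooth rather than a hard threshold, which is what a phyloP-like
score sharing information with, but not determined by, methylation
conservation looks like — and it is what makes the bin curve's monotone trend
a meaningful recovery target.

Default scale is 2 contigs × 1 Mb per species (≈ 4000 windows, 900 planted
tsDMRs), chosen so the full generate-plus-analyse cycle completes in well
under a minute on one core while keeping binomial noise on recovered
fractions near 1.5 percentage points.  What passing recovery shows: the
pipeline's rules invert the generator's planting exactly (classification
agrees with planted flags with zero mismatches at default noise).  What it
does not show: robustness to features real data has and the generator lacks —
read-level noise, non-CG methylation, cell-type heterogeneity, repeat-driven
mapping ambiguity, GC/CpG covariation with conservation, and realistic TE
structure.

## Numerical and degenerate-input choices

* Percentages round half away from zero to match printed tables.
* χ² on a table with a zero margin returns NaN rather than raising; such
  strata are excluded from BH correction.
* Liftover of an interval no chain aligns returns an unmapped result with
  covered fraction 0, never an error; malformed files raise `FormatError`
  with the offending line or chain id.
* Score-bin ties break by genomic position; matched/GC sampling is seeded;
  chain choice ties break by chain id — every analysis is rerun-identical.
* The three-state categorization rejects levels outside [0, 1]; region means
  over zero CpGs are undefined (None), not 0.

## Known limitations

* Single-best-chain mapping (no split mapping across chains), no net/axt
  support, and no reciprocal-best filtering.
* The upstream DMR model and single-CpG predictor are consumed as inputs
  (q-values, levels), not implemented.
* Known-motif scanning only; no de novo discovery, and exact consensus
  matching is stricter than log-odds scanning with permissive thresholds.
* Strand-merged CpG positions are assumed; non-CG methylation is not
  modelled.
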