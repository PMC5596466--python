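# epicons

Cross-species conservation analysis of tissue-specific DNA methylation.

Tissue identity is written into the methylome: each tissue carries thousands
of short genomic windows that are hypomethylated in that tissue alone
(tissue-specific differentially methylated regions, **tsDMRs**), and many of
them mark enhancers and promoters.  `epicons` asks to what extent these
tissue-specific methylation patterns are *conserved between species* — the
phenomenon of **epigenetic conservation** — and how far plain sequence
conservation and transcription-factor binding-site (TFBS) turnover explain
it.  It is aimed at comparative epigenomics analyses of the rat/mouse/human
kind (three species × three shared tissues), but every stage is an ordinary
library function over standard file formats.

## What it computes

1. **tsDMR calling.**  On 500-bp windows with per-tissue mean methylation
   m_t ∈ [0,1], a window is a tsDMR for tissue *t* when either
   m_t < 0.3 and m_{t'} ≥ 0.3 for both other tissues (criterion 1), or
   0.3 ≤ m_t ≤ 0.7 and m_{t'} > 0.7 for both others (criterion 2),
   optionally gated by an upstream differential-methylation q-value < 1e-5.
2. **Orthology mapping.**  UCSC chain-file liftover with a 50% source-coverage
   requirement and a 1000-bp cap on the mapped span; three-way orthologs
   require the direct A→C image and the composed A→B→C image to agree by
   ≥ 90% overlap of the shorter image.
3. **EC/ENC classification.**  Methylation status is categorical
   (unmethylated < 0.3, intermediate, methylated > 0.7).  An ortholog is
   **EC** (epigenetically conserved) iff its status triple repeats the
   tissue-specific pattern: target 0 with others ∈ {1,2}, or target 1 with
   both others 2; otherwise **ENC**.  Enrichment over a random-region
   background is an upper-tail hypergeometric test.
4. **Genetic conservation.**  Element overlap (≥ 20% of the window) and a
   per-base conservation-score analysis: each tsDMR is split into 50-bp
   subwindows, the mean score of each mapped subwindow is computed, the
   subwindows are sorted into 100 equal-sized score bins, and the EC fraction
   is reported per bin.
5. **Feature-matched enrichment.**  Genomic-feature labelling (> 50%
   coverage, fixed precedence), composition-matched background sampling,
   distance-to-TSS and feature-distribution folds with Pearson χ² and
   Benjamini–Hochberg correction, histone-peak summit overlap, and signal
   profiles around region midpoints.
6. **Motif turnover.**  IUPAC-consensus (or PWM) scanning on both strands;
   GC-matched background enrichment split by EC status; and per-ortholog-pair
   classification of each motif's fate: conserved in place, turnover (present
   on both sides but not positionally aligned), loss, or gain.
7. **Synthetic benchmark.**  A seeded generator emits a full three-species
   trio (genomes, chains, methylomes, annotations, score tracks, peaks,
   motifs) with known ground truth for every stage, so the whole pipeline is
   testable end to end.

## Worked example

```python
from epicons import SimulationConfig, simulate_trio
from epicons.pipeline import run_trio
from epicons.simulate import recovery_report

cfg = SimulationConfig(seed=42, n_contigs=1, contig_length=400_000,
                       n_dmrs_per_tissue=80, n_unmethylated_windows=30)
bundle = simulate_trio(cfg, "demo_trio")
result = run_trio(bundle, curve_bins=25)
print(result.tables["rat_to_mouse"].to_string(index=False))
rep = recovery_report(result, bundle)
```

prints

```
tissue  n_tsdmr  n_ec  n_enc  percent_ec
 blood       80    34     43          43
 brain       80    27     52          34
 sperm       80    24     52          30
```

i.e. 80 tsDMRs called per tissue (all planted windows recovered), of which
34/27/24 have a mouse ortholog repeating the tissue pattern — 43/34/30%
epigenetic conservation against a planted rate of 30% at this small n.  The
recovery report scores the run against the generator's truth table:

```
tsDMR recall: 1.000
estimated EC fraction (rat-mouse): 0.366 (planted 0.30)
turnover precision/recall: 0.99/0.96
score-bin EC trend (Spearman rho): 0.95
```

The same stages are exposed on the command line
(`epicons simulate | call-dmrs | liftover | threeway | classify-ec |
phylop-bins | motif-scan | motif-turnover`); enrichment statistics are used
as library calls, e.g.

```python
from epicons import nearest_tss, distance_enrichment, summit_overlap
```

## Layout

```
src/epicons/
  intervals.py     coordinates, BED/chain/wig/genePred/FASTA I/O
  methylome.py     CpG tracks, region means, three-state status
  tsdmr.py         tsDMR calling
  orthology.py     liftover and three-way orthologs
  conservation.py  EC/ENC classification, tables, hypergeometric test
  genetic.py       element overlap and score-binned EC curve
  enrichment.py    features, matched backgrounds, χ²/BH, summits, profiles
  motifs.py        consensus/PWM scanning, GC-matched enrichment, turnover
  simulate.py      synthetic trio generator + recovery scoring
  pipeline.py      end-to-end orchestration over a bundle
  cli.py           command-line entry points
```

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
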