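# Methods

`eleanor-scan` implements a windowed RNA-seq screen for gene loci whose
mRNA and surrounding noncoding RNA (ncRNA) are coordinately regulated
across a three-condition adaptation design: a baseline state (A), an
adapted state after hormone deprivation (B), and a drug-treated state (C).
The archetype is the ESR1 locus in long-term oestrogen-deprived breast
cancer cells, where intronic and upstream ncRNAs ("Eleanors") rise
together with ESR1 mRNA on deprivation and fall together on resveratrol
treatment, while short loci such as ERBB2 show the same mRNA pattern
without any ncRNA response.

## Pipeline model

1. **Window counting.** Aligned reads (BED6 intervals) are assigned by
   midpoint to fixed-width windows (default 100 bp, non-overlapping
   tiling). Windows start at every multiple of the step below the
   chromosome length; the last window is truncated. With tiling, each read
   is counted exactly once, so window column sums equal library sizes —
   the property median-of-ratios normalisation relies on. Overlapping
   windows (step < width) are supported but flagged, because their counts
   are statistically dependent in testing. Counting is strand-separated by
   default (the ncRNAs of interest are sense-strand).

2. **Normalisation.** DESeq-style median-of-ratios size factors,
   rescaled to geometric mean 1. The pipeline estimates them from
   gene-level exon-union counts rather than the window matrix: gene counts
   are high (tight count ratios) and mostly non-differential, whereas
   window rows are sparse and, at desk scale, heavily enriched for the
   planted signal. This inherits the standard global-normalisation
   assumption that non-differential genes are the majority.

3. **Differential testing.** A negative-binomial exact test with
   variance mean + α·mean². The test conditions on the pooled total
   N = K_A + K_B and sums, over all N + 1 splits, the probabilities no
   larger than the observed split's, normalised by the total; probability
   ties (within 1e-10 relative tolerance in log space) all count towards
   rejection — deterministic and conservative. For α < 1e-5 the NB mass is
   evaluated as its Poisson limit, which is numerically exact there
   (gammaln differences of ~1/α-sized arguments would otherwise lose ~9
   significant digits). Windows are labelled up/down by the strict gate
   |log2FC| > 1 together with p < 0.01 on raw p-values (the procedure's
   historical gate); BH-adjusted values are always reported alongside.
   log2FC uses a symmetric pseudocount of 0.5 on normalised condition
   means.

4. **Dispersion.** Three estimators are provided, with different
   robustness/power trade-offs:
   * `pooled` — per-feature method of moments on within-condition
     variability; requires replicates.
   * `blind` — per-feature method of moments pooling all samples as one
     group. Valid with no replicates, but any real effect inflates the
     feature's own estimate, so it is very conservative: a feature with a
     true 4-fold change acquires α̂ ≈ 0.6 and can never reach p < 0.01.
     Useful for calibration studies, not for discovery.
   * `common` (default for no-replicate designs) — one dispersion shared
     by all features, the median-calibrated global moment estimate. A
     per-feature variance statistic v whose null law is σ²·V for a fixed
     pivot V satisfies median(v / median(V)) = σ², so
     t = (v/median(V) − m̄·mean)/mean² has conditional median exactly α
     and the global median of t estimates α without distributional bias.
     In the canonical 3-sample design, v is the *minimum pairwise*
     squared difference / 2 (Monte-Carlo median constant 0.06515 for the
     Gaussian pivot): any feature differential in at most one condition —
     including the up-then-down adaptation pattern, whose baseline and
     treated states agree — retains a null-like closest pair, so
     differential features do not contaminate the estimate regardless of
     how many there are or where their means lie. Features with mean < 5
     are excluded from the estimate (their moment statistics are too
     granular) but still receive the shared value. Limitations: features
     genuinely differential in *all three* conditions (monotone drift)
     would leak into the estimate, and a single shared α ignores any real
     mean-dispersion trend.
   A binned-median mean-dispersion trend was considered and rejected:
   binning by pooled mean systematically segregates differential features
   into their own bins (their pooled means are shifted by the effect), so
   at desk scale the trend learns the effect as dispersion.

5. **Region building and classification.** Significant windows of one
   direction merge when adjacent (or within `max_gap`, default 0) on the
   same chromosome and strand; region statistics are the supporting window
   count, the count-weighted mean log2FC and the minimum p. Each region is
   classified against the annotation: no gene overlap → `intergene`;
   otherwise the host is the gene with maximal span overlap (ties broken
   by smallest gene id), and the region is `complete_exon` (no non-exonic
   bases), `exon_intron` (both exonic and non-exonic bases) or `intron`
   (no exonic bases). Because window grids quantise region ends, a purely
   exonic transcript systematically overhangs its exons by up to one
   window per side; classification therefore accepts a `tolerance` (bp)
   below which exonic or non-exonic overlap counts as zero. The library
   default is 0 (strict per-base rules); the pipeline passes
   2·(window − 1). Everything except `complete_exon` is an ncRNA
   candidate; their share of all regions is reported as a percentage
   (undefined, not zero, for an empty region set).

6. **The co-regulation screen.** Genic ncRNA regions belong to their host
   gene; intergenic regions are assigned to the nearest gene whose TSS
   lies downstream on the same strand within `upstream_flank` (default
   50 kb, covering enhancer-like upstream transcripts ~40 kb out with
   margin). A gene is **coordinated** when its mRNA is up in A→B *and*
   down in B→C *and* it has ≥ 1 assigned ncRNA region up in A→B *and*
   ≥ 1 down in B→C; genes passing only the mRNA pattern are
   **mrna_only**; the rest are **other**. mRNA calls come from gene-level
   counts over exon unions (midpoint-in-exon, strand-matched), tested with
   the same NB machinery. The four underlying gene sets are also
   summarised as a four-way Venn pattern table. For each coordinated locus
   a transcribed chromatin domain is called: the minimal interval covering
   the gene span plus every assigned ncRNA region chainable to it through
   gaps ≤ `bridge_gap` (default 10 kb; regions can chain through one
   another, regions beyond an unbridged gap are excluded). Gene length is
   genomic span (end − start); group length summaries use the arithmetic
   mean rounded half-up. The packaged reference table of 26 human genes
   (13 coordinated-regulation loci, mean span 280,065 bp by direct
   computation; 13 mRNA-only loci, mean 16,839 bp) serves as a fixture for
   the length arithmetic.

7. **Expression-pattern clustering.** Gene FPKM
   (count / (exonic kb × mapped reads in millions)) per condition;
   genes pass the filter when the interquartile range of the three
   condition values exceeds 10 (linear-interpolation quartiles) and the
   maximum exceeds 5, both strict. Profiles are row z-scored (patterns,
   not magnitudes) and clustered by k-means (k-means++ init, best of 50
   restarts, deterministic under seed; default k = 14, clamped to the
   number of filtered genes when a small run cannot support it). The
   induced-then-repressed set is extracted by centroid shape (middle
   condition the maximum), never by cluster index, since k-means numbering
   is arbitrary.

## Synthetic data

The generator plants the full effect structure on a toy genome so every
stage is testable without downloads:

* **coordinated** long genes (span uniform 280 kb ± 25%, ≥ 8 exons,
  ESR1-like): mRNA log2FC +2 in A→B and −2 in B→C; intronic ncRNA at 0.3×
  the exonic level with the same ±2 pattern; an upstream ncRNA element
  (2 kb wide, 40 kb before the TSS, same strand) co-regulated with the
  introns. The planted domain is the gene span extended to the upstream
  element.
* **mrna_only** short genes (17 kb ± 25%, ≥ 2 exons, ERBB2-like): the
  same mRNA pattern, constant intragenic signal.
* **null** genes: constant expression. One silent gene (zero expression,
  SYNE1-like) sits immediately downstream of each coordinated gene; the
  other nulls are expressed, mostly long (80%), with constitutive
  intragenic transcription at a per-gene log-uniform 0.1–1.0 × exonic
  level. This wide constitutive range mirrors pervasive transcription in
  real genomes and keeps non-differential windows in the majority at every
  expression level — the condition both median-of-ratios normalisation
  and common-dispersion estimation need; a simulation containing only the
  planted loci would make any data-driven normalisation ill-posed.

Default expression scale: 200 exonic reads/kb per sample at unit depth
(~20 reads per exonic 100-bp tile), per-gene lognormal baseline variation
(cv 0.5), intergenic background 0.05 reads/tile, NB dispersion α = 0.02
(a no-replicate, same-culture technical-noise regime). Counts are drawn
per 100-bp tile and then materialised as 50-bp stranded reads placed
uniformly within the tile, so the counting stage sees exactly the
intended NB structure; gene-level sums over many tiles are consequently
near-Poisson. Genes are placed with ≥ 2× upstream-offset spacing (so
upstream elements never collide) on an auto-sized chromosome; a
configured chromosome length too small for the roster raises a sizing
error naming the required minimum. The default roster is 5 coordinated,
5 mRNA-only and 20 null genes (~6 Mb, ~1M reads over three samples), one
sample per condition — the no-replicate design the original experiment
used; replicates are configurable.

What the generator does **not** emulate: sequence content (no FASTA/
FASTQ, no alignment errors or multimapping), splice-aware coverage
shapes, fragment-length effects, biological replicate variability at the
gene level, antisense transcription, or overlapping genes. Passing tests
therefore demonstrate the pipeline's statistical and interval logic under
the stated noise model, not robustness to alignment artefacts.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; GTF I/O is the
  single 1-based inclusive conversion boundary; BED is native.
* Published interval boundaries quoted as coordinate pairs are treated as
  half-open boundaries (length = end − start); e.g. the ncRNA-associated
  domain 151,720,000–152,424,447 on 6q25.1 spans 704,447 bp (~700 kb).
* Fold-change sign convention: log2FC = later/earlier condition, "up"
  means higher in the later condition.
* The exact test returns p = 1 for a zero pooled total; p-values are
  clipped to (0, 1].
* Host-gene ties and k-means numbering are resolved deterministically;
  one global seed fans out to per-stage seeds by stage-name hashing, so
  stages rerun in isolation reproduce the full run; identical
  configuration and seed give byte-identical reports.
* Scaling one sample's counts and size factor by the same constant leaves
  normalised means and log2FC exactly invariant, but not exact-test
  p-values: the test conditions on the raw pooled total, which such
  scaling changes. This is inherent to the conditioned test.
* The screen's desk-scale study conditions (roster, rates, ±2 effects)
  are fixed in `SimulationConfig`; pipeline runs at these defaults
  recover planted coordinated loci with sensitivity ~1.0, no null genes
  called coordinated, and called domains overlapping planted domains at
  Jaccard ≈ 0.87 (the 40-kb upstream gap exceeds the 10-kb bridge gap, so
  the upstream element is deliberately outside the called domain).

## Known limitations

* The exon–intron category is positional; junction reads are invisible to
  window counting, so retained-intron-like signal and boundary-spanning
  transcription are not distinguished.
* Genome-scale results of the original study (e.g. 168k differential
  regions, ncRNA fractions of 63.8%/67.3%, 2,918 filtered genes) depend
  on the full human dataset and are not desk-scale reproducible; the
  pipeline's claims at desk scale are the property-based ones above. The
  simulated ncRNA fraction (~94%) exceeds the published range because the
  toy genome is dominated by long intron-rich loci.
* Gene-level counting requires that exons of distinct genes do not
  overlap on one strand (true for the generator and for flattened
  single-isoform annotations).
* With fewer than ~10 mostly-null genes, median-of-ratios normalisation
  degrades (the differential minority assumption fails) and downstream
  calls with it.
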