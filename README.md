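# eleanor-scan

A bulk RNA-seq pipeline for finding gene loci whose mRNA **and**
surrounding noncoding RNA are coordinately regulated across a
three-condition adaptation design (baseline → hormone-deprived →
drug-treated). The motivating biology is the ESR1 locus in oestrogen-
deprivation-adapted breast cancer cells: on adaptation, a cluster of
noncoding RNAs ("Eleanors") is induced from the introns and the upstream
enhancer-like region of the locus, together with ESR1 mRNA, defining a
~700-kb transcribed chromatin domain; both fall together on treatment.
Short loci such as ERBB2 show the same mRNA pattern with no ncRNA
response. `eleanor-scan` is for computational biologists who want that
screen as a tested, reusable library and command line, runnable end to
end on built-in synthetic data.

## What it computes

* **Window counts** — reads assigned by midpoint to 100-bp windows
  (stranded, tiled by default).
* **Differential calls** — a negative-binomial exact test (variance
  μ + αμ²) conditioned on the pooled total N:

      p = Σ{ Pr(a, N−a) ≤ Pr(K_A, K_B) } Pr(a, N−a) / Σ_a Pr(a, N−a)

  with size factors from median-of-ratios normalisation and a dispersion
  α estimated per feature (with replicates) or shared across features via
  a robust median-calibrated estimate (no replicates). Windows are
  labelled up/down by |log2FC| > 1 and p < 0.01.
* **Region classes** — significant windows merged into regions and
  classified against the annotation as complete_exon / exon_intron /
  intron / intergene; everything except complete_exon is an ncRNA
  candidate.
* **The co-regulation screen** — a gene is *coordinated* when its mRNA is
  up in A→B, down in B→C, and it has assigned ncRNA regions up in A→B and
  down in B→C (intergenic regions attach to a downstream TSS within a
  50-kb upstream flank). Per coordinated locus a transcribed chromatin
  domain is called by chaining ncRNA regions to the gene span through
  gaps ≤ 10 kb.
* **Pattern clusters** — gene FPKM profiles filtered by IQR > 10 and
  FPKM > 5, z-scored and k-means clustered; the induced-then-repressed
  gene set is extracted by centroid shape.

The synthetic-data module plants all of this structure (ESR1-like long
coordinated genes with intronic + 40-kb-upstream ncRNA, ERBB2-like
mRNA-only genes, silent SYNE1-like neighbours, NB count noise) so the
whole pipeline runs and is tested without any download.

## Worked example

One command simulates a 30-gene, ~7.6-Mb genome (5 coordinated long
genes, 5 mRNA-only short genes, 20 nulls; one sample per condition) and
runs every stage:

```sh
eleanor-scan run --seed 1 --outdir demo
```

`demo/report.txt` from that exact command:

```
genes: 30  genome: 7598435 bp
  reads baseline_1: 288891
  reads deprived_1: 584884
  reads treated_1: 288876
baseline_vs_deprived: windows up/down 3964/12, genes up/down 10/0
deprived_vs_treated: windows up/down 24/3813, genes up/down 0/10
baseline_vs_deprived: 2502 regions, ncRNA fraction 89.57%
deprived_vs_treated: 2439 regions, ncRNA fraction 88.89%
verdicts: {'coordinated': 5, 'mrna_only': 5, 'other': 20}
coordinated: coordinated_01, ..., coordinated_05
  coordinated: n=5 mean length 277260 bp
  mrna_only: n=5 mean length 16168 bp
recovery: sensitivity 1.0, null false calls 0
```

Reading it: the deprived sample carries ~2× the reads (the induced
ncRNA); ~3,900 windows rise on adaptation and ~3,800 fall on treatment,
and the ten regulated genes are called up then down at the gene level.
Merged regions are ~89% ncRNA candidates (the toy genome is dominated by
intron-rich loci). The screen recovers exactly the five planted
coordinated loci — long genes, mean span 277 kb, versus 16 kb for the
mRNA-only group, reproducing the long-gene signature of coordinated
ncRNA/mRNA regulation — with no null gene called coordinated.
`demo/` also holds the window counts, per-contrast differential tables,
classified region BEDs, the four-way Venn table, called domains and the
cluster assignments; `demo/report.json` is the machine-readable report,
byte-identical for identical seed and configuration.

Individual stages are available as `eleanor-scan
simulate|count|de|classify|screen|cluster`, and everything is importable:

```python
from eleanor_scan import PipelineConfig, SimulationConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=1, simulate=SimulationConfig()))
report["stages"]["screen"]["verdicts"]
# {'coordinated': 5, 'mrna_only': 5, 'other': 20}
```

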