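"""Synthetic genome, annotation and stranded read generator with planted loci.

The generator emulates the three-condition breast-cancer adaptation design
(baseline culture -> hormone deprivation -> drug treatment) at desk scale:

* a small number of *coordinated* long genes (ESR1-like, ~280 kb span,
  >= 8 exons) whose mRNA **and** intronic/upstream ncRNA rise ~4-fold in the
  deprived condition and fall back on treatment;
* *mrna_only* short genes (ERBB2-like, ~17 kb) whose mRNA shows the same
  up-then-down pattern but whose intragenic signal stays constant;
* *null* genes split into expressed genes (constant mRNA, constant low-level
  constitutive intragenic transcription — pervasive transcription keeps
  differential loci a minority, which data-driven normalisation and
  dispersion-trend estimation require) and one *silent* neighbour placed
  immediately downstream of each coordinated gene (SYNE1-like: background
  counts only, in every condition);
* an upstream ncRNA element ~40 kb before each coordinated gene's promoter
  (u-Eleanor-like), co-regulated with the intragenic signal.

Counts are drawn per 100-bp tile from a negative binomial
(variance = mean + alpha * mean^2) and then materialised as fixed-length
stranded reads placed uniformly within the tile, so the window-counting
stage downstream sees exactly the intended NB structure.  All randomness is
driven by one seed; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    introns_of,
    write_annotation,
    write_bed6,
)

CONDITIONS = ("baseline", "deprived", "treated")

GENE_KINDS = ("coordinated", "mrna_only", "null")


class SizingError(ValueError):
    """The configured chromosome is too small for the gene roster."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic three-condition experiment.

    Rates are expected read counts at unit depth; ``baseline_rate`` is the
    exonic expression level in reads per kb per sample, so a gene expressed
    at the default 200 reads/kb yields ~20 reads per 100-bp exonic tile.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int | None = None  # auto-sized when None

    # gene roster
    n_coordinated: int = 5
    n_mrna_only: int = 5
    n_null: int = 20
    null_long_fraction: float = 0.8  # of expressed null genes, drawn long

    # gene geometry
    long_span_mean: int = 280_000  # ESR1-like span
    short_span_mean: int = 17_000  # ERBB2-like span
    span_jitter: float = 0.25  # spans uniform in mean * (1 +/- jitter)
    long_min_exons: int = 8
    short_min_exons: int = 2
    exon_length_range: tuple[int, int] = (1_000, 2_000)

    # expression model
    baseline_rate: float = 200.0  # exonic reads per kb per sample at depth 1
    baseline_cv: float = 0.5  # lognormal per-gene variation of the baseline
    ncrna_fraction: float = 0.3  # regulated intragenic level vs exonic level
    # constant intragenic transcription of non-coordinated expressed genes:
    # per-gene level log-uniform in this range (x exonic level), emulating the
    # wide dynamic range of constitutive/pervasive intragenic signal
    constitutive_range: tuple[float, float] = (0.1, 1.0)
    background_rate: float = 0.05  # mean intergenic reads per tile per sample
    dispersion: float = 0.02  # NB alpha; 0 -> Poisson

    # planted effects (log2 fold changes)
    lfc_ab_mrna: float = 2.0
    lfc_bc_mrna: float = -2.0
    lfc_ab_ncrna: float = 2.0
    lfc_bc_ncrna: float = -2.0

    # upstream ncRNA element (u-Eleanor-like)
    upstream_offset: int = 40_000  # gap between element end and the TSS
    upstream_width: int = 2_000

    # sequencing
    n_replicates: int = 1
    depth: float | Sequence[float] = 1.0  # per-sample scale (scalar or per sample)
    read_length: int = 50
    tile: int = 100

    def __post_init__(self):
        if self.tile < 1 or self.read_length < 1:
            raise ValueError("tile and read_length must be >= 1")
        for name in ("baseline_rate", "long_span_mean", "short_span_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dispersion < 0 or self.background_rate < 0:
            raise ValueError("dispersion and background_rate must be >= 0")
        for lfc in (self.lfc_ab_mrna, self.lfc_bc_mrna,
                    self.lfc_ab_ncrna, self.lfc_bc_ncrna):
            if not np.isfinite(lfc):
                raise ValueError("planted fold changes must be finite")
        depths = self.depths()
        if np.any(np.asarray(depths) <= 0):
            raise ValueError("depths must be > 0")

    @property
    def samples(self) -> list[str]:
        return [
            f"{cond}_{r + 1}"
            for cond in CONDITIONS
            for r in range(self.n_replicates)
        ]

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{cond}_{r + 1}", "condition": cond}
            for cond in CONDITIONS
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows)

    def depths(self) -> np.ndarray:
        n = len(CONDITIONS) * self.n_replicates
        d = np.asarray(self.depth, dtype=float)
        if d.ndim == 0:
            return np.full(n, float(d))
        if d.shape != (n,):
            raise ValueError(f"depth must be scalar or length {n}")
        return d

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["depth"] = list(np.atleast_1d(np.asarray(self.depth, dtype=float)))
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SimulationTruth:
    """Ground truth for one simulated dataset.

    ``genes`` has one row per gene: kind, baseline rate, planted mRNA/ncRNA
    log2 fold changes, silent flag and (for coordinated genes) the planted
    domain interval.  ``rates`` holds the expected per-tile read count per
    condition at unit depth, chromosome by chromosome — the exact means the
    NB draws use.
    """

    genes: pd.DataFrame
    rates: dict[str, np.ndarray]  # chrom -> (n_tiles, n_conditions)
    tile_strand: dict[str, np.ndarray]  # chrom -> per-tile strand code (+,-,.)
    tile: int

    def domain_of(self, gene_id: str) -> GenomicInterval | None:
        row = self.genes.set_index("gene_id").loc[gene_id]
        if not np.isfinite(row["domain_start"]):
            return None
        return GenomicInterval(
            row["chrom"], int(row["domain_start"]), int(row["domain_end"]),
            row["strand"],
        )


def _draw_span(rng: np.random.Generator, mean: int, jitter: float) -> int:
    lo, hi = int(mean * (1 - jitter)), int(mean * (1 + jitter))
    return int(rng.integers(lo, hi + 1))


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    span: int,
    min_exons: int,
    exon_range: tuple[int, int],
    strand: str,
) -> GeneModel:
    """Random exon structure: first exon at the start, last ending at the end."""
    n_exons = int(rng.integers(min_exons, min_exons + 5))
    lo, hi = exon_range
    lengths = rng.integers(lo, hi + 1, size=n_exons)
    # keep exonic total under half the span so introns dominate long genes
    while lengths.sum() > span // 2 and n_exons > 2:
        n_exons -= 1
        lengths = lengths[:n_exons]
    if lengths.sum() >= span:
        lengths = np.maximum(1, span // (2 * n_exons)) * np.ones(n_exons, dtype=int)
    intron_total = span - int(lengths.sum())
    n_gaps = n_exons - 1
    if n_gaps == 0:
        gaps = np.array([], dtype=int)
    else:
        w = rng.dirichlet(np.ones(n_gaps))
        gaps = np.maximum(1, np.floor(w * intron_total).astype(int))
        gaps[-1] += intron_total - int(gaps.sum())  # absorb rounding in last gap
        if gaps[-1] < 1:
            gaps = np.maximum(1, intron_total // n_gaps) * np.ones(n_gaps, dtype=int)
            gaps[-1] = intron_total - int(gaps[:-1].sum())
    exons = []
    pos = start
    for i, ln in enumerate(lengths):
        exons.append(GenomicInterval(chrom, pos, pos + int(ln), strand))
        pos += int(ln)
        if i < n_gaps:
            pos += int(gaps[i])
    interval = GenomicInterval(chrom, start, start + span, strand)
    return GeneModel(gene_id, interval, tuple(exons))


def _roster(config: SimulationConfig) -> list[dict]:
    """Ordered gene specs: kind, span class, silent flag, pairing."""
    n_silent = min(config.n_coordinated, config.n_null)
    n_expressed_null = config.n_null - n_silent
    n_null_long = int(round(config.null_long_fraction * n_expressed_null))
    specs = []
    for i in range(config.n_coordinated):
        specs.append({"kind": "coordinated", "long": True, "silent": False,
                      "pair_silent": i < n_silent})
    for _ in range(config.n_mrna_only):
        specs.append({"kind": "mrna_only", "long": False, "silent": False,
                      "pair_silent": False})
    for j in range(n_expressed_null):
        specs.append({"kind": "null", "long": j < n_null_long, "silent": False,
                      "pair_silent": False})
    return specs


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Lay out non-overlapping genes with >= 2x upstream-offset spacing.

    Deterministic under ``config.seed``.  Raises :class:`SizingError` when a
    configured ``chrom_length`` cannot hold the roster; the error names the
    required minimum.
    """
    annotation, _ = simulate_annotation_with_truth(config)
    return annotation


def simulate_annotation_with_truth(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, SimulationTruth]:
    """Annotation plus the planted ground truth derived alongside it."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    specs = _roster(config)
    order = rng.permutation(len(specs))
    margin = 2 * config.upstream_offset + config.upstream_width

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    # round-robin assignment of gene units to chromosomes
    per_chrom: dict[str, list[dict]] = {c: [] for c in chrom_names}
    for k, idx in enumerate(order):
        per_chrom[chrom_names[k % config.n_chroms]].append(specs[idx])

    genes: list[GeneModel] = []
    truth_rows: list[dict] = []
    sizes: dict[str, int] = {}
    gid = {"coordinated": 0, "mrna_only": 0, "null": 0, "silent": 0}

    for chrom in chrom_names:
        pos = margin
        for spec in per_chrom[chrom]:
            entries = [spec]
            if spec["pair_silent"]:
                entries.append({"kind": "null", "long": False, "silent": True})
            for entry in entries:
                long = entry["long"]
                span = _draw_span(
                    rng,
                    config.long_span_mean if long else config.short_span_mean,
                    config.span_jitter,
                )
                strand = "+" if rng.random() < 0.5 else "-"
                if entry["silent"]:
                    gid["silent"] += 1
                    gene_id = f"silent_{gid['silent']:02d}"
                else:
                    gid[entry["kind"]] += 1
                    gene_id = f"{entry['kind']}_{gid[entry['kind']]:02d}"
                gene = _make_gene(
                    rng, gene_id, chrom, pos, span,
                    config.long_min_exons if long else config.short_min_exons,
                    config.exon_length_range, strand,
                )
                genes.append(gene)
                if entry["silent"]:
                    baseline = 0.0
                else:
                    baseline = config.baseline_rate * float(
                        rng.lognormal(mean=0.0, sigma=config.baseline_cv)
                    )
                coord = entry["kind"] == "coordinated"
                lo, hi = config.constitutive_range
                const_fraction = 0.0 if (coord or entry["silent"]) else float(
                    np.exp(rng.uniform(np.log(lo), np.log(hi)))
                )
                if coord:
                    if strand == "+":
                        up_start = gene.interval.start - config.upstream_offset \
                            - config.upstream_width
                        up_end = up_start + config.upstream_width
                        dom = (up_start, gene.interval.end)
                    else:
                        up_start = gene.interval.end + config.upstream_offset
                        up_end = up_start + config.upstream_width
                        dom = (gene.interval.start, up_end)
                else:
                    up_start = up_end = np.nan
                    dom = (np.nan, np.nan)
                truth_rows.append({
                    "gene_id": gene_id,
                    "kind": entry["kind"],
                    "silent": bool(entry["silent"]),
                    "chrom": chrom,
                    "start": gene.interval.start,
                    "end": gene.interval.end,
                    "strand": strand,
                    "span": span,
                    "baseline_rate": baseline,
                    "const_fraction": const_fraction,
                    "lfc_ab_mrna": config.lfc_ab_mrna if not entry["silent"]
                    and entry["kind"] != "null" else 0.0,
                    "lfc_bc_mrna": config.lfc_bc_mrna if not entry["silent"]
                    and entry["kind"] != "null" else 0.0,
                    "lfc_ab_ncrna": config.lfc_ab_ncrna if coord else 0.0,
                    "lfc_bc_ncrna": config.lfc_bc_ncrna if coord else 0.0,
                    "upstream_start": up_start,
                    "upstream_end": up_end,
                    "domain_start": dom[0],
                    "domain_end": dom[1],
                })
                gap = int(rng.integers(2 * config.upstream_offset,
                                       int(2.5 * config.upstream_offset) + 1))
                pos += span + gap
        required = pos + margin
        if config.chrom_length is not None:
            if config.chrom_length < required:
                raise SizingError(
                    f"{chrom}: configured length {config.chrom_length} too small; "
                    f"roster needs at least {required} bp"
                )
            sizes[chrom] = config.chrom_length
        else:
            sizes[chrom] = required

    annotation = GenomeAnnotation(sizes, genes)
    truth = _build_truth(config, annotation, pd.DataFrame(truth_rows))
    return annotation, truth


def _add_interval_rate(
    rates: np.ndarray, tile: int, start: int, end: int, per_tile: np.ndarray
) -> None:
    """Add ``per_tile`` (one value per condition) to tiles covering [start, end),
    pro-rated by the covered fraction of each tile."""
    t0, t1 = start // tile, (end - 1) // tile
    for t in range(t0, t1 + 1):
        ov = min(end, (t + 1) * tile) - max(start, t * tile)
        rates[t] += per_tile * (ov / tile)


def _build_truth(
    config: SimulationConfig, annotation: GenomeAnnotation, genes_df: pd.DataFrame
) -> SimulationTruth:
    n_cond = len(CONDITIONS)
    rates: dict[str, np.ndarray] = {}
    tile_strand: dict[str, np.ndarray] = {}
    tile = config.tile
    for chrom, size in annotation.chrom_sizes.items():
        n_tiles = (size + tile - 1) // tile
        rates[chrom] = np.full((n_tiles, n_cond), config.background_rate)
        tile_strand[chrom] = np.full(n_tiles, ".", dtype=object)

    def cond_multipliers(lfc_ab: float, lfc_bc: float) -> np.ndarray:
        return np.array([1.0, 2.0 ** lfc_ab, 2.0 ** (lfc_ab + lfc_bc)])

    for row in genes_df.itertuples():
        gene = annotation.gene(row.gene_id)
        chrom_rates = rates[gene.chrom]
        strand_arr = tile_strand[gene.chrom]
        t0, t1 = gene.interval.start // tile, (gene.interval.end - 1) // tile
        strand_arr[t0:t1 + 1] = gene.strand
        if row.silent or row.baseline_rate == 0.0:
            continue
        exonic_per_tile = row.baseline_rate * tile / 1000.0
        m_mrna = cond_multipliers(row.lfc_ab_mrna, row.lfc_bc_mrna)
        for ex in gene.exons:
            _add_interval_rate(chrom_rates, tile, ex.start, ex.end,
                               exonic_per_tile * m_mrna)
        if row.kind == "coordinated":
            nc_per_tile = config.ncrna_fraction * exonic_per_tile
            m_nc = cond_multipliers(row.lfc_ab_ncrna, row.lfc_bc_ncrna)
        else:
            nc_per_tile = row.const_fraction * exonic_per_tile
            m_nc = np.ones(n_cond)
        for intr in introns_of(gene):
            _add_interval_rate(chrom_rates, tile, intr.start, intr.end,
                               nc_per_tile * m_nc)
        if row.kind == "coordinated":
            us, ue = int(row.upstream_start), int(row.upstream_end)
            _add_interval_rate(chrom_rates, tile, us, ue, nc_per_tile * m_nc)
            ut0, ut1 = us // tile, (ue - 1) // tile
            strand_arr[ut0:ut1 + 1] = gene.strand
    return SimulationTruth(genes=genes_df, rates=rates, tile_strand=tile_strand,
                           tile=tile)


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """NB(mean, variance = mean + alpha mean^2) counts; Poisson when alpha = 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_reads(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
) -> dict[str, pd.DataFrame]:
    """Per-sample BED6 read sets drawn from the planted per-tile means.

    Counts per tile per sample are NB(depth * expected mean, dispersion);
    read starts are uniform within the tile; strand follows the gene for
    genic/upstream tiles and is random for intergenic background.
    """
    samples = config.samples
    depths = config.depths()
    cond_index = {c: i for i, c in enumerate(CONDITIONS)}
    sheet = config.sample_sheet()
    out: dict[str, pd.DataFrame] = {}
    ss = np.random.SeedSequence([config.seed, 202])
    child = {s: np.random.default_rng(seq)
             for s, seq in zip(samples, ss.spawn(len(samples)))}
    for j, sample in enumerate(samples):
        rng = child[sample]
        cond = sheet.loc[sheet["sample"] == sample, "condition"].iloc[0]
        ci = cond_index[cond]
        frames = []
        for chrom in annotation.chrom_sizes:
            means = truth.rates[chrom][:, ci] * depths[j]
            counts = _nb_draw(rng, means, config.dispersion)
            total = int(counts.sum())
            if total == 0:
                continue
            tiles = np.repeat(np.arange(counts.size), counts)
            starts = tiles * config.tile + rng.integers(
                0, config.tile, size=total
            )
            L = annotation.chrom_sizes[chrom]
            starts = np.minimum(starts, L - 1)
            ends = np.minimum(starts + config.read_length, L)
            strands = truth.tile_strand[chrom][tiles].astype(object)
            bg = strands == "."
            if bg.any():
                strands[bg] = np.where(
                    rng.random(int(bg.sum())) < 0.5, "+", "-"
                )
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "start": starts.astype(np.int64),
                "end": ends.astype(np.int64),
                "name": [f"{sample}_r{i}" for i in range(total)],
                "score": 0,
                "strand": strands.astype(str),
            }))
        if frames:
            df = pd.concat(frames, ignore_index=True)
        else:
            df = pd.DataFrame({
                "chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64), "name": pd.Series(dtype=str),
                "score": pd.Series(dtype=int), "strand": pd.Series(dtype=str),
            })
        out[sample] = df
    return out


def simulate_count_matrix(
    n_features: int,
    mean: float,
    alpha: float,
    n_samples: int,
    seed: int,
    mean_cv: float = 0.0,
) -> pd.DataFrame:
    """A no-effect NB count matrix (every sample shares each feature's mean).

    Used for null-calibration studies; ``mean_cv > 0`` adds lognormal
    feature-to-feature variation of the mean.
    """
    rng = np.random.default_rng(seed)
    mu = np.full(n_features, float(mean))
    if mean_cv > 0:
        mu *= rng.lognormal(0.0, mean_cv, size=n_features)
    counts = np.column_stack([
        _nb_draw(rng, mu, alpha) for _ in range(n_samples)
    ])
    cols = [f"s{j + 1}" for j in range(n_samples)]
    return pd.DataFrame(counts, columns=cols)


def write_simulation(
    outdir,
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    reads: Mapping[str, pd.DataFrame],
) -> dict[str, str]:
    """Materialise GTF, chrom sizes, per-sample BED6, truth TSV and config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": str(outdir / "annotation.gtf"),
        "sizes": str(outdir / "chrom.sizes"),
        "truth": str(outdir / "truth.tsv"),
        "config": str(outdir / "config.json"),
        "sample_sheet": str(outdir / "samples.tsv"),
    }
    write_annotation(annotation, paths["annotation"], paths["sizes"])
    truth.genes.to_csv(paths["truth"], sep="\t", index=False)
    Path(paths["config"]).write_text(config.to_json() + "\n")
    config.sample_sheet().to_csv(paths["sample_sheet"], sep="\t", index=False)
    for sample, df in reads.items():
        p = outdir / f"reads_{sample}.bed"
        write_bed6(df, p)
        paths[f"reads_{sample}"] = str(p)
    return paths
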