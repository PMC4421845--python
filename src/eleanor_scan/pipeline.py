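"""End-to-end orchestration: simulate -> count -> test -> classify -> screen
-> cluster, with one global seed, deterministic stage seeds and a run report.

The pipeline estimates one set of size factors from the window-count matrix
and shares it across window- and gene-level testing, so both views of the
library are normalised consistently.  Window regions are classified with a
quantisation tolerance of 2 * (window - 1) bp (see region_class).  The
clustering stage clamps k to the number of filtered genes when a small run
cannot support the default of 14; the report records the value used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coreg_screen, diffexpr, profile_cluster, region_class
from .genome_model import GenomeAnnotation, GenomicInterval, read_annotation, read_bed6, write_bed6
from .synthetic_data import (
    CONDITIONS,
    SimulationConfig,
    SimulationTruth,
    simulate_annotation_with_truth,
    simulate_reads,
    write_simulation,
)
from .window_counts import count_gene_reads, count_reads, make_grid

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed by hashing the stage name: stages rerun in isolation
    reproduce the full run."""
    return (zlib.crc32(f"{global_seed}:{stage}".encode()) ^ global_seed) % (2**31)


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs (simulated or on disk) + stage knobs."""

    seed: int = 0
    outdir: str | None = None

    # inputs: either a simulation config, or paths to annotation + reads
    simulate: SimulationConfig | None = None
    annotation_path: str | None = None
    sizes_path: str | None = None
    read_paths: dict[str, str] | None = None  # sample -> BED6
    sample_sheet_path: str | None = None

    # stage parameters (module defaults)
    window: int = 100
    step: int | None = None
    strand_mode: str = "stranded_same"
    lfc_thr: float = 1.0
    p_thr: float = 0.01
    pseudocount: float = 0.5
    alpha_floor: float = diffexpr.DEFAULT_FLOOR
    dispersion_mode: str | None = None  # None -> auto per design
    max_gap: int = 0
    upstream_flank: int = 50_000
    bridge_gap: int = 10_000
    iqr_min: float = 10.0
    fpkm_min: float = 5.0
    k: int = 14
    kmeans_restarts: int = 50

    contrasts: tuple[tuple[str, str], ...] = (
        (CONDITIONS[0], CONDITIONS[1]),
        (CONDITIONS[1], CONDITIONS[2]),
    )

    def validate(self) -> None:
        if self.simulate is None and (
            self.annotation_path is None or self.sizes_path is None
            or self.read_paths is None or self.sample_sheet_path is None
        ):
            raise ValueError(
                "provide either a simulation config or annotation/sizes/reads/"
                "sample-sheet paths"
            )


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _echo_params(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # run location, not analysis configuration
    if config.simulate is not None:
        d["simulate"] = json.loads(config.simulate.to_json())
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return (and optionally write) the run report.

    The report is a plain dict: parameter echo, per-stage feature counts,
    ncRNA fractions per contrast, the coordinated-locus table, length
    summaries by verdict, cluster summary and — when ground truth exists —
    recovery metrics.  Identical config and seed give identical reports.
    """
    config.validate()
    report: dict = {"parameters": _echo_params(config), "stages": {}}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    truth: SimulationTruth | None = None
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(
                config.simulate, seed=stage_seed(config.seed, "simulate")
            )
            annotation, truth = simulate_annotation_with_truth(sim)
            reads = simulate_reads(sim, annotation, truth)
            sheet = sim.sample_sheet()
            if outdir:
                write_simulation(outdir / "sim", sim, annotation, truth, reads)
        else:
            annotation = read_annotation(config.annotation_path, config.sizes_path)
            reads = {s: read_bed6(p) for s, p in config.read_paths.items()}
            sheet = pd.read_csv(config.sample_sheet_path, sep="\t")
        report["stages"]["inputs"] = {
            "n_genes": len(annotation),
            "n_chromosomes": len(annotation.chrom_sizes),
            "genome_bp": int(sum(annotation.chrom_sizes.values())),
            "samples": {s: int(len(df)) for s, df in reads.items()},
        }

        stage = "count"
        grid = make_grid(annotation, width=config.window, step=config.step,
                         strand_mode=config.strand_mode)
        wcm = count_reads(reads, grid)
        gene_counts, exonic_len = count_gene_reads(
            reads, annotation, stranded=config.strand_mode == "stranded_same"
        )
        if outdir:
            wcm.to_tsv(outdir / "window_counts.tsv")
            gene_counts.to_csv(outdir / "gene_counts.tsv", sep="\t")
        report["stages"]["count"] = {
            "n_windows": int(len(wcm.features)),
            "nonzero_windows": int((wcm.counts.sum(axis=1) > 0).sum()),
            "skipped_reads": {s: int(v) for s, v in wcm.skipped.items()},
        }

        stage = "normalize"
        # gene-level counts are high and mostly non-differential, so the
        # median-of-ratios there is far more stable than on sparse windows
        size_factors = diffexpr.estimate_size_factors(gene_counts)
        report["stages"]["normalize"] = {
            "size_factors": {s: round(float(v), 6)
                             for s, v in size_factors.items()},
        }

        stage = "de"
        # with no replicates the common dispersion is estimated once across
        # all three conditions: the min-pair statistic needs the full design
        # to see that up-then-down features have a null-like closest pair
        reps = sheet["condition"].value_counts().min()
        window_disp = gene_disp = None
        if config.dispersion_mode is None and reps < 2:
            conds = [sheet.set_index("sample")["condition"][s]
                     for s in wcm.samples]
            window_disp = diffexpr.estimate_dispersion(
                pd.DataFrame(wcm.counts, columns=wcm.samples), size_factors,
                conditions=conds, mode="common", floor=config.alpha_floor,
            )
            gene_disp = diffexpr.estimate_dispersion(
                gene_counts, size_factors,
                conditions=[sheet.set_index("sample")["condition"][s]
                            for s in gene_counts.columns],
                mode="common", floor=config.alpha_floor,
            )
        window_de: dict[str, pd.DataFrame] = {}
        gene_de: dict[str, pd.DataFrame] = {}
        de_stats: dict[str, dict] = {}
        for c1, c2 in config.contrasts:
            key = f"{c1}_vs_{c2}"
            wde = diffexpr.diff_regions(
                wcm, sheet, (c1, c2),
                lfc_thr=config.lfc_thr, p_thr=config.p_thr,
                pseudocount=config.pseudocount, size_factors=size_factors,
                dispersion=window_disp,
                dispersion_mode=config.dispersion_mode,
                alpha_floor=config.alpha_floor,
            )
            gde = diffexpr.diff_genes(
                gene_counts, sheet, (c1, c2),
                lfc_thr=config.lfc_thr, p_thr=config.p_thr,
                pseudocount=config.pseudocount, size_factors=size_factors,
                dispersion=gene_disp,
                dispersion_mode=config.dispersion_mode,
                alpha_floor=config.alpha_floor,
            )
            window_de[key] = wde
            gene_de[key] = gde
            de_stats[key] = {
                "windows_tested": int(len(wde)),
                "windows_up": int((wde["label"] == "up").sum()),
                "windows_down": int((wde["label"] == "down").sum()),
                "genes_up": int((gde["label"] == "up").sum()),
                "genes_down": int((gde["label"] == "down").sum()),
            }
            if outdir:
                wde.to_csv(outdir / f"windows_de_{key}.tsv", sep="\t",
                           index=False)
                gde.to_csv(outdir / f"genes_de_{key}.tsv", sep="\t")
        report["stages"]["de"] = de_stats

        stage = "classify"
        tolerance = 2 * (config.window - 1)
        regions: dict[str, pd.DataFrame] = {}
        ncrna: dict[str, pd.DataFrame] = {}
        cls_stats: dict[str, dict] = {}
        for key, wde in window_de.items():
            merged = region_class.merge_windows(wde, max_gap=config.max_gap)
            classified = region_class.classify_regions(
                merged, annotation,
                stranded=config.strand_mode == "stranded_same",
                tolerance=tolerance,
            )
            nc, frac = region_class.ncrna_candidates(classified)
            nc = coreg_screen.assign_regions(nc, annotation,
                                             config.upstream_flank)
            regions[key] = classified
            ncrna[key] = nc
            cls_stats[key] = {
                "n_regions": int(len(classified)),
                "by_class": {k: int(v) for k, v in
                             classified.get("region_class", pd.Series(dtype=str))
                             .value_counts().items()},
                "ncrna_fraction_pct": None if np.isnan(frac)
                else round(float(frac), 2),
            }
            if outdir and len(classified):
                write_bed6(
                    region_class.regions_to_bed(classified)[
                        ["chrom", "start", "end", "name", "score", "strand"]
                    ],
                    outdir / f"regions_{key}.bed",
                )
        report["stages"]["classify"] = cls_stats

        stage = "screen"
        key_ab = f"{config.contrasts[0][0]}_vs_{config.contrasts[0][1]}"
        key_bc = f"{config.contrasts[1][0]}_vs_{config.contrasts[1][1]}"
        loci = coreg_screen.coregulation_screen(
            gene_de[key_ab], gene_de[key_bc], ncrna[key_ab], ncrna[key_bc],
            annotation, bridge_gap=config.bridge_gap,
        )
        venn = coreg_screen.four_way_venn({
            "mrna_up_ab": set(gene_de[key_ab].index[
                gene_de[key_ab]["label"] == "up"]),
            "ncrna_up_ab": set(ncrna[key_ab].loc[
                (ncrna[key_ab]["direction"] == "up")
                & ncrna[key_ab]["gene_id"].notna(), "gene_id"]),
            "mrna_down_bc": set(gene_de[key_bc].index[
                gene_de[key_bc]["label"] == "down"]),
            "ncrna_down_bc": set(ncrna[key_bc].loc[
                (ncrna[key_bc]["direction"] == "down")
                & ncrna[key_bc]["gene_id"].notna(), "gene_id"]),
        })
        lengths_by_verdict = {
            v: sorted(loci.loc[loci["verdict"] == v, "length_bp"].astype(int))
            for v in coreg_screen.VERDICTS
        }
        lengths = coreg_screen.length_summary(lengths_by_verdict)
        if outdir:
            loci.to_csv(outdir / "coordinated_loci.tsv", sep="\t", index=False)
            venn.to_csv(outdir / "venn_patterns.tsv", sep="\t", index=False)
            lengths.to_csv(outdir / "length_summary.tsv", sep="\t", index=False)
            dom = loci[loci["verdict"] == "coordinated"].dropna(
                subset=["domain_start"])
            if len(dom):
                write_bed6(pd.DataFrame({
                    "chrom": dom["domain_chrom"],
                    "start": dom["domain_start"].astype(int),
                    "end": dom["domain_end"].astype(int),
                    "name": dom["gene_id"],
                    "score": 0,
                    "strand": ".",
                }), outdir / "domains.bed")
        report["stages"]["screen"] = {
            "n_genes_screened": int(len(loci)),
            "verdicts": {v: int((loci["verdict"] == v).sum())
                         for v in coreg_screen.VERDICTS},
            "coordinated_genes": sorted(
                loci.loc[loci["verdict"] == "coordinated", "gene_id"]),
            "length_summary": {
                row["group"]: {"n": int(row["n"]),
                               "mean_length_bp": None if row["n"] == 0
                               else int(row["mean_length_bp"])}
                for _, row in lengths.iterrows()
            },
            "venn": {row["pattern"]: int(row["count"])
                     for _, row in venn.iterrows()},
        }

        stage = "cluster"
        if (wcm.totals <= 0).any():
            report["stages"]["cluster"] = {
                "n_filtered": 0, "note": "samples without mapped reads",
            }
            if truth is not None:
                report["recovery"] = recovery_metrics(loci, truth)
            _finish(report, outdir)
            return report
        fpkm = profile_cluster.compute_fpkm(gene_counts, exonic_len, wcm.totals)
        profiles = profile_cluster.condition_means(fpkm, sheet, list(CONDITIONS))
        filtered = profile_cluster.filter_genes(
            profiles, iqr_min=config.iqr_min, fpkm_min=config.fpkm_min)
        cluster_report: dict = {"n_filtered": int(len(filtered))}
        if len(filtered) >= 2:
            k = min(config.k, len(filtered))
            if k < config.k:
                logger.info("clamping k from %d to %d (filtered genes)",
                            config.k, k)
            assignment = profile_cluster.kmeans_cluster(
                filtered, k=k, seed=stage_seed(config.seed, "cluster"),
                restarts=config.kmeans_restarts,
            )
            pattern_genes = profile_cluster.extract_pattern(
                assignment, "up_then_down")
            cluster_report.update({
                "k_used": k,
                "up_then_down_genes": sorted(pattern_genes),
            })
            if outdir:
                fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
                assignment.labels.to_csv(outdir / "clusters.tsv", sep="\t")
                assignment.centroids.to_csv(outdir / "centroids.tsv", sep="\t")
        report["stages"]["cluster"] = cluster_report

        if truth is not None:
            report["recovery"] = recovery_metrics(loci, truth)
    except Exception as exc:  # noqa: BLE001 - report which stage failed
        if outdir:
            (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageFailure(stage, exc) from exc

    _finish(report, outdir)
    return report


def _finish(report: dict, outdir: Path | None) -> None:
    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        (outdir / "report.txt").write_text(_human_report(report))


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = max(a.end, b.end) - min(a.start, b.start)
    return inter / union if union else 0.0


def recovery_metrics(loci: pd.DataFrame, truth: SimulationTruth) -> dict:
    """Sensitivity/false-call rates and domain overlap against planted truth."""
    tg = truth.genes.set_index("gene_id")
    called = set(loci.loc[loci["verdict"] == "coordinated", "gene_id"])
    true_coord = set(tg.index[tg["kind"] == "coordinated"])
    null_genes = set(tg.index[tg["kind"] == "null"])
    recovered = called & true_coord
    jacs = []
    by_gene = loci.set_index("gene_id")
    for gid in sorted(recovered):
        planted = truth.domain_of(gid)
        row = by_gene.loc[gid]
        if planted is None or not np.isfinite(row["domain_start"]):
            continue
        dom = GenomicInterval(row["domain_chrom"], int(row["domain_start"]),
                              int(row["domain_end"]))
        jacs.append(jaccard(dom, planted))
    return {
        "sensitivity": len(recovered) / len(true_coord) if true_coord else None,
        "n_true_coordinated": len(true_coord),
        "n_recovered": len(recovered),
        "null_false_coordinated": len(called & null_genes),
        "mrna_only_called_coordinated": len(
            called & set(tg.index[tg["kind"] == "mrna_only"])),
        "domain_jaccards": [round(j, 4) for j in jacs],
        "frac_domains_jaccard_ge_0.8": (
            sum(j >= 0.8 for j in jacs) / len(jacs) if jacs else None
        ),
    }


def _human_report(report: dict) -> str:
    lines = ["eleanor-scan run report", "======================", ""]
    stages = report["stages"]
    inp = stages.get("inputs", {})
    lines.append(f"genes: {inp.get('n_genes')}  genome: {inp.get('genome_bp')} bp")
    for s, n in inp.get("samples", {}).items():
        lines.append(f"  reads {s}: {n}")
    for key, st in stages.get("de", {}).items():
        lines.append(
            f"{key}: windows up/down {st['windows_up']}/{st['windows_down']}, "
            f"genes up/down {st['genes_up']}/{st['genes_down']}"
        )
    for key, st in stages.get("classify", {}).items():
        lines.append(
            f"{key}: {st['n_regions']} regions, ncRNA fraction "
            f"{st['ncrna_fraction_pct']}%"
        )
    sc = stages.get("screen", {})
    lines.append(f"verdicts: {sc.get('verdicts')}")
    lines.append(f"coordinated: {', '.join(sc.get('coordinated_genes', []))}")
    for grp, s in sc.get("length_summary", {}).items():
        lines.append(f"  {grp}: n={s['n']} mean length {s['mean_length_bp']} bp")
    if "recovery" in report:
        rec = report["recovery"]
        lines.append(
            f"recovery: sensitivity {rec['sensitivity']}, "
            f"null false calls {rec['null_false_coordinated']}"
        )
    return "\n".join(lines) + "\n"
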