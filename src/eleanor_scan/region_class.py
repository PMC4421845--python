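"""Merge significant windows into regions and classify them against genes.

Classes mirror the four-way split used for differential read clusters:
``complete_exon`` (fully exonic within the host gene), ``exon_intron``
(mixed exonic and non-exonic signal — retained-intron-like), ``intron``
(entirely intronic) and ``intergene`` (no gene overlap).  Everything except
``complete_exon`` is a noncoding-RNA candidate.

Window grids quantise region ends to window boundaries, so a purely exonic
transcript systematically produces regions overhanging its exons by up to
one window on each side.  ``classify_region`` therefore accepts a
``tolerance`` (bp): exonic or non-exonic overlaps no larger than it are
treated as zero before the decision rules fire.  The default of 0 applies
the strict per-base rules; the pipeline passes 2 * (window - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomeAnnotation, GenomicInterval, overlap_bp

logger = logging.getLogger(__name__)

REGION_CLASSES = ("complete_exon", "exon_intron", "intron", "intergene")


def merge_windows(
    diff: pd.DataFrame,
    max_gap: int = 0,
) -> pd.DataFrame:
    """Merge same-direction significant windows into regions.

    ``diff`` is a window-level differential table (chrom, start, end,
    strand, log2fc, pvalue, label, mean_* columns).  Windows labelled "up"
    or "down" merge when on the same chromosome and strand, in the same
    direction, and separated by at most ``max_gap`` bp (0 merges only
    adjacent or overlapping windows).  Region statistics: supporting window
    count, count-weighted mean log2FC (weights: summed normalised condition
    means, with a 1e-9 guard so all-zero weights fall back to unweighted),
    and the minimum p-value.
    """
    sig = diff[diff["label"].isin(["up", "down"])]
    if sig.empty:
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "strand", "direction",
            "n_windows", "log2fc", "min_p",
        ])
    mean_cols = [c for c in diff.columns if c.startswith("mean_")]
    rows = []
    for (chrom, strand, direction), grp in sig.groupby(
        ["chrom", "strand", "label"], sort=True
    ):
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        lfc = grp["log2fc"].to_numpy()
        pv = grp["pvalue"].to_numpy()
        wt = grp[mean_cols].to_numpy().sum(axis=1) + 1e-9
        cur = 0
        cur_end = ends[0]
        for i in range(1, len(grp) + 1):
            if i < len(grp) and starts[i] - cur_end <= max_gap:
                cur_end = max(cur_end, ends[i])
                continue
            sl = slice(cur, i)
            rows.append({
                "chrom": chrom,
                "start": int(starts[cur]),
                "end": int(cur_end),
                "strand": strand,
                "direction": direction,
                "n_windows": i - cur,
                "log2fc": float(np.average(lfc[sl], weights=wt[sl])),
                "min_p": float(pv[sl].min()),
            })
            if i < len(grp):
                cur = i
                cur_end = ends[i]
    out = pd.DataFrame(rows).sort_values(
        ["chrom", "start", "end", "strand", "direction"]
    ).reset_index(drop=True)
    return out


def _exonic_overlap(region: GenomicInterval, gene: GeneModel) -> int:
    return sum(overlap_bp(region, ex) for ex in gene.exons)


def classify_region(
    region: GenomicInterval,
    annotation: GenomeAnnotation,
    stranded: bool = True,
    tolerance: int = 0,
) -> tuple[str, str | None]:
    """Assign one of the four region classes plus the host gene.

    Decision order: (1) no overlapping gene -> ``intergene`` with no host;
    otherwise the host is the gene with maximal span overlap (ties broken
    by lexicographically smallest gene id, logged); then with e = exonic
    bases of the region in the host and x = remaining region bases
    (intronic or outside the span), both thresholded to zero when <=
    ``tolerance``: e > 0 and x > 0 -> ``exon_intron``; x == 0 ->
    ``complete_exon``; e == 0 -> ``intron``.  In stranded mode only genes
    on the region's strand can host it (unstranded regions match any gene).
    """
    strand = region.strand if (stranded and region.strand in "+-") else None
    hits = annotation.genes_overlapping(
        region.chrom, region.start, region.end, strand=strand
    )
    if not hits:
        return "intergene", None
    overlaps = [(overlap_bp(region, g.interval), g.gene_id) for g in hits]
    best = max(ov for ov, _ in overlaps)
    tied = sorted(gid for ov, gid in overlaps if ov == best)
    if len(tied) > 1:
        logger.info("host-gene tie for %s: %s; keeping %s",
                    region, tied, tied[0])
    host = annotation.gene(tied[0])
    e = _exonic_overlap(region, host)
    x = region.length - e
    e_eff = 0 if e <= tolerance else e
    x_eff = 0 if x <= tolerance else x
    if e_eff > 0 and x_eff > 0:
        cls = "exon_intron"
    elif x_eff == 0 and e > 0:
        cls = "complete_exon"
    elif e_eff == 0 and x > 0:
        cls = "intron"
    else:  # degenerate: region smaller than tolerance on both counts
        cls = "complete_exon" if e >= x else "intron"
    return cls, host.gene_id


def classify_regions(
    regions: pd.DataFrame,
    annotation: GenomeAnnotation,
    stranded: bool = True,
    tolerance: int = 0,
) -> pd.DataFrame:
    """Vector version of :func:`classify_region` over a merged-region table."""
    classes, hosts = [], []
    for row in regions.itertuples():
        iv = GenomicInterval(row.chrom, row.start, row.end,
                             row.strand if row.strand in "+-" else ".")
        cls, host = classify_region(iv, annotation, stranded=stranded,
                                    tolerance=tolerance)
        classes.append(cls)
        hosts.append(host)
    out = regions.copy()
    out["region_class"] = classes
    out["host_gene"] = hosts
    return out


def ncrna_candidates(regions: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Regions that are not fully exonic, plus their share as a percentage.

    The fraction is NaN (not 0) for an empty input.
    """
    if "region_class" not in regions.columns:
        raise ValueError("regions must be classified first")
    if len(regions) == 0:
        return regions.copy(), float("nan")
    subset = regions[regions["region_class"] != "complete_exon"]
    fraction = 100.0 * len(subset) / len(regions)
    return subset.reset_index(drop=True), fraction


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """BED6+ representation: name = class, score = -log10 min p."""
    score = -np.log10(np.maximum(regions["min_p"].to_numpy(), 1e-300))
    return pd.DataFrame({
        "chrom": regions["chrom"],
        "start": regions["start"],
        "end": regions["end"],
        "name": regions.get("region_class", pd.Series(["region"] * len(regions))),
        "score": np.round(score, 3),
        "strand": regions["strand"],
        "host_gene": regions.get("host_gene"),
        "direction": regions["direction"],
    })
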