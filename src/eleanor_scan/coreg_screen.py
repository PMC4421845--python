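"""The headline screen: genes whose mRNA and assigned ncRNA move together.

A gene is *coordinated* when its mRNA is up-regulated in the adaptation
contrast (A -> B), down-regulated in the treatment contrast (B -> C), and
at least one assigned ncRNA region is up in A -> B and at least one is
down in B -> C.  Genes passing only the mRNA criterion are *mrna_only*;
everything else is *other*.  ncRNA regions belong to their host gene when
genic, and intergenic regions are attributed to the nearest gene whose
transcription start lies downstream on the same strand within an upstream
flank (enhancer-like upstream transcripts).

For each coordinated locus a transcribed chromatin domain is called: the
minimal interval covering the gene span plus every assigned ncRNA region
chainable to it through gaps of at most ``bridge_gap`` bp.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import GenomeAnnotation, GenomicInterval

logger = logging.getLogger(__name__)

VERDICTS = ("coordinated", "mrna_only", "other")


def assign_region_to_gene(
    region: pd.Series | dict,
    annotation: GenomeAnnotation,
    upstream_flank: int = 50_000,
) -> str | None:
    """Gene a classified region belongs to, or None.

    Genic classes keep their host gene.  Intergenic regions go to the
    nearest gene (same strand unless the region is unstranded) whose TSS is
    downstream of the region within ``upstream_flank`` bp; ties on distance
    break by lexicographic gene id.
    """
    cls = region["region_class"]
    if cls != "intergene":
        return region["host_gene"]
    chrom, start, end = region["chrom"], int(region["start"]), int(region["end"])
    strand = region.get("strand", ".")
    best: tuple[int, str] | None = None
    for g in annotation.genes_on(chrom):
        if strand in "+-" and g.strand != strand:
            continue
        if g.strand == "-":
            gap = start - g.interval.end
        else:
            gap = g.interval.start - end
        if 0 <= gap <= upstream_flank:
            cand = (gap, g.gene_id)
            if best is None or cand < best:
                best = cand
    return best[1] if best else None


def assign_regions(
    regions: pd.DataFrame,
    annotation: GenomeAnnotation,
    upstream_flank: int = 50_000,
) -> pd.DataFrame:
    out = regions.copy()
    out["gene_id"] = [
        assign_region_to_gene(row, annotation, upstream_flank)
        for _, row in regions.iterrows()
    ]
    return out


def four_way_venn(sets: dict[str, set]) -> pd.DataFrame:
    """Counts of the 15 non-empty membership patterns of four gene sets.

    Every element of the union lands in exactly one pattern.  The result
    has one row per pattern (a '1'/'0' string in the order of ``sets``)
    with the member count; patterns of sets beyond four work the same way.
    """
    names = list(sets)
    union = set().union(*sets.values()) if sets else set()
    patterns: dict[str, int] = {}
    for x in union:
        key = "".join("1" if x in sets[n] else "0" for n in names)
        patterns[key] = patterns.get(key, 0) + 1
    rows = [
        {"pattern": k, "count": v,
         "sets": "&".join(n for n, bit in zip(names, k) if bit == "1")}
        for k, v in sorted(patterns.items())
    ]
    return pd.DataFrame(rows, columns=["pattern", "sets", "count"])


def call_domain(
    gene_interval: GenomicInterval,
    regions: pd.DataFrame,
    bridge_gap: int = 10_000,
) -> GenomicInterval:
    """Minimal interval covering the gene span and chainable ncRNA regions.

    Starting from the gene span, any region within ``bridge_gap`` bp of the
    current domain (on the gene's chromosome) extends it; extension repeats
    until stable, so regions can chain through one another.  Regions beyond
    an unbridged gap are excluded.
    """
    start, end = gene_interval.start, gene_interval.end
    ivs = [
        (int(r.start), int(r.end))
        for r in regions.itertuples()
        if r.chrom == gene_interval.chrom
    ]
    changed = True
    while changed:
        changed = False
        remaining = []
        for s, e in ivs:
            if s - end <= bridge_gap and start - e <= bridge_gap:
                ns, ne = min(start, s), max(end, e)
                if (ns, ne) != (start, end):
                    changed = True
                start, end = ns, ne
            else:
                remaining.append((s, e))
        ivs = remaining
    return GenomicInterval(gene_interval.chrom, start, end, gene_interval.strand)


def coregulation_screen(
    mrna_ab: pd.DataFrame,
    mrna_bc: pd.DataFrame,
    ncrna_ab: pd.DataFrame,
    ncrna_bc: pd.DataFrame,
    annotation: GenomeAnnotation,
    bridge_gap: int = 10_000,
) -> pd.DataFrame:
    """Per-gene coordination verdicts, sorted by gene length descending.

    ``mrna_ab``/``mrna_bc`` are gene-level differential tables (indexed by
    gene id with a ``label`` column); ``ncrna_ab``/``ncrna_bc`` are
    classified ncRNA-candidate regions with a ``gene_id`` assignment and a
    ``direction`` column.  Unknown gene ids raise ``KeyError`` naming the id.
    """
    for df in (mrna_ab, mrna_bc):
        for gid in df.index:
            if gid not in annotation.genes:
                raise KeyError(f"gene id {gid!r} in differential table but not "
                               "in annotation")
    lab_ab = mrna_ab["label"]
    lab_bc = mrna_bc["label"]
    nc_up_ab = ncrna_ab[(ncrna_ab["direction"] == "up")
                        & ncrna_ab["gene_id"].notna()]
    nc_dn_bc = ncrna_bc[(ncrna_bc["direction"] == "down")
                        & ncrna_bc["gene_id"].notna()]
    for df in (nc_up_ab, nc_dn_bc):
        for gid in df["gene_id"]:
            if gid not in annotation.genes:
                raise KeyError(f"gene id {gid!r} assigned to a region but not "
                               "in annotation")
    genes = sorted(
        set(lab_ab.index) | set(lab_bc.index)
        | set(nc_up_ab["gene_id"]) | set(nc_dn_bc["gene_id"])
    )
    up_counts = nc_up_ab.groupby("gene_id").size()
    dn_counts = nc_dn_bc.groupby("gene_id").size()
    rows = []
    for gid in genes:
        gene = annotation.gene(gid)
        m_ab = lab_ab.get(gid, "ns")
        m_bc = lab_bc.get(gid, "ns")
        n_up = int(up_counts.get(gid, 0))
        n_dn = int(dn_counts.get(gid, 0))
        mrna_pattern = m_ab == "up" and m_bc == "down"
        if mrna_pattern and n_up >= 1 and n_dn >= 1:
            verdict = "coordinated"
        elif mrna_pattern:
            verdict = "mrna_only"
        else:
            verdict = "other"
        domain = None
        gene_regions = pd.concat([
            nc_up_ab[nc_up_ab["gene_id"] == gid],
            nc_dn_bc[nc_dn_bc["gene_id"] == gid],
        ])
        if len(gene_regions):
            domain = call_domain(gene.interval, gene_regions, bridge_gap)
        rows.append({
            "gene_id": gid,
            "length_bp": gene.length,
            "mrna_ab": m_ab,
            "mrna_bc": m_bc,
            "n_ncrna_up_ab": n_up,
            "n_ncrna_down_bc": n_dn,
            "verdict": verdict,
            "domain_chrom": domain.chrom if domain else None,
            "domain_start": domain.start if domain else np.nan,
            "domain_end": domain.end if domain else np.nan,
        })
    out = pd.DataFrame(rows, columns=[
        "gene_id", "length_bp", "mrna_ab", "mrna_bc", "n_ncrna_up_ab",
        "n_ncrna_down_bc", "verdict", "domain_chrom", "domain_start",
        "domain_end",
    ])
    return out.sort_values(
        ["length_bp", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)


def length_summary(groups: dict[str, list[int]]) -> pd.DataFrame:
    """Group sizes and arithmetic mean lengths, rounded half-up to 1 bp.

    Empty groups report n = 0 and an undefined (NaN) mean.
    """
    rows = []
    for name, lengths in groups.items():
        n = len(lengths)
        if n:
            mean = math.floor(sum(lengths) / n + 0.5)
        else:
            mean = float("nan")
        rows.append({"group": name, "n": n, "mean_length_bp": mean})
    return pd.DataFrame(rows, columns=["group", "n", "mean_length_bp"])


def load_reference_gene_table() -> pd.DataFrame:
    """Published reference table of 26 human genes: 13 with coordinated
    ncRNA/mRNA regulation (long, ESR1 among them) and 13 with mRNA-only
    regulation, with genomic lengths in bp."""
    ref = importlib.resources.files("eleanor_scan.data") \
        .joinpath("coordinated_gene_lengths.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def reference_length_summary() -> pd.DataFrame:
    """Length summary of the packaged reference gene table, per group."""
    tab = load_reference_gene_table()
    groups = {
        name: list(grp["length_bp"])
        for name, grp in tab.groupby("group", sort=True)
    }
    return length_summary(groups)
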