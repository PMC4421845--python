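import numpy as np
import pandas as pd
import pytest

from eleanor_scan.genome_model import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
)


def make_gene(gene_id, chrom, exon_coords, strand="+"):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords)
    interval = GenomicInterval(chrom, exon_coords[0][0], exon_coords[-1][1], strand)
    return GeneModel(gene_id, interval, exons)


@pytest.fixture
def two_exon_gene():
    return make_gene("g1", "chr1", [(0, 100), (200, 300)])


@pytest.fixture
def eight_exon_gene():
    # 8 exons of 100 bp separated by 900-bp introns: span 7,100 bp
    coords = [(i * 1000, i * 1000 + 100) for i in range(8)]
    return make_gene("g8", "chr1", coords)


@pytest.fixture
def toy_annotation(eight_exon_gene):
    """One 8-exon gene, one short 2-exon gene downstream, one gene on chr2."""
    short = make_gene("short", "chr1", [(20_000, 20_500), (21_500, 22_000)])
    minus = make_gene("rev", "chr2", [(5_000, 5_400), (6_000, 6_500)], strand="-")
    return GenomeAnnotation(
        {"chr1": 50_000, "chr2": 20_000},
        [eight_exon_gene, short, minus],
    )


def random_annotation(rng, chrom_len=100_000, n_genes=6):
    """Genes with random exon structures, non-overlapping, both strands."""
    genes = []
    pos = int(rng.integers(0, 2_000))
    for i in range(n_genes):
        n_ex = int(rng.integers(1, 5))
        exons = []
        for j in range(n_ex):
            length = int(rng.integers(50, 500))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(100, 800))
        pos = exons[-1][1] + int(rng.integers(500, 3_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i}", "chr1", exons, strand))
    return GenomeAnnotation({"chr1": max(chrom_len, pos + 1000)}, genes)


@pytest.fixture
def sample_sheet3():
    return pd.DataFrame({
        "sample": ["baseline_1", "deprived_1", "treated_1"],
        "condition": ["baseline", "deprived", "treated"],
    })
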