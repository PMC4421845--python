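"""Genomic coordinate system, gene models, interval arithmetic and annotation I/O.

All coordinates are held internally as 0-based, half-open intervals
(``start`` inclusive, ``end`` exclusive), the BED convention.  The single
place where conventions are converted is the GTF reader/writer, which maps
to and from GTF's 1-based inclusive coordinates.  Keeping one conversion
boundary eliminates off-by-one ambiguity everywhere else.

A :class:`GeneModel` flattens all transcripts of a gene to a single exon
union: the analyses built on top operate at gene-region level (exon vs
intron vs intergenic base classes), not at isoform level.  Gene length is
genomic span (``end - start``), i.e. the quantity reported for loci such as
ESR1 (412,778 bp), not the exonic sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class AnnotationError(ValueError):
    """Invalid coordinates or inconsistent annotation content."""


class GtfParseError(AnnotationError):
    """A GTF line could not be parsed; carries the 1-based line number."""

    def __init__(self, path, lineno: int, reason: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}: line {lineno}: {reason}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a named chromosome.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if on different chromosomes).

    Half-open convention: touching intervals such as (0,100) and (100,200)
    share no base.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene as a genomic span plus a flattened, ordered exon union.

    Invariants enforced at construction:

    * exons are sorted, strictly separated (``prev.end < next.start``) and on
      the gene's chromosome and strand;
    * the first exon starts at ``interval.start`` and the last ends at
      ``interval.end`` (the span is the exon-union hull);
    * consequently ``sum(exon lengths) + sum(intron lengths) == length``.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self):
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon {ex} not on gene chrom/strand"
                )
            if not self.interval.contains(ex):
                raise AnnotationError(f"gene {self.gene_id}: exon {ex} outside span")
            if prev is not None and ex.start <= prev.end - 1:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons unsorted or overlapping near {ex}"
                )
            prev = ex
        if self.exons[0].start != self.interval.start:
            raise AnnotationError(
                f"gene {self.gene_id}: first exon does not start at gene start"
            )
        if self.exons[-1].end != self.interval.end:
            raise AnnotationError(
                f"gene {self.gene_id}: last exon does not end at gene end"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        """Genomic span in bp (end - start)."""
        return self.interval.length

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware; 0-based)."""
        return self.interval.start if self.strand != "-" else self.interval.end - 1


def introns_of(gene: GeneModel) -> list[GenomicInterval]:
    """The gaps between consecutive exons, in genomic order.

    A single-exon gene has no introns; an n-exon gene has n - 1.
    """
    out = []
    for a, b in zip(gene.exons, gene.exons[1:]):
        out.append(GenomicInterval(gene.chrom, a.end, b.start, gene.strand))
    return out


class GenomeAnnotation:
    """Chromosome sizes plus a collection of genes, indexed by id and position."""

    def __init__(self, chrom_sizes: Mapping[str, int], genes: Iterable[GeneModel]):
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise AnnotationError(f"chromosome {name}: non-positive length {size}")
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {g.gene_id}")
            if g.chrom not in self.chrom_sizes:
                raise AnnotationError(
                    f"gene {g.gene_id}: chromosome {g.chrom} not in size table"
                )
            if g.interval.end > self.chrom_sizes[g.chrom]:
                raise AnnotationError(
                    f"gene {g.gene_id}: end {g.interval.end} beyond chromosome "
                    f"{g.chrom} length {self.chrom_sizes[g.chrom]}"
                )
            self.genes[g.gene_id] = g
        self._trees: dict[str, IntervalTree] | None = None
        self._by_chrom: dict[str, list[GeneModel]] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(f"gene id {gene_id!r} not in annotation") from None

    def gene_length(self, gene_id: str) -> int:
        return self.gene(gene_id).length

    def _ensure_index(self) -> None:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            by_chrom: dict[str, list[GeneModel]] = {}
            for g in self.genes.values():
                trees.setdefault(g.chrom, IntervalTree()).addi(
                    g.interval.start, g.interval.end, g.gene_id
                )
                by_chrom.setdefault(g.chrom, []).append(g)
            for lst in by_chrom.values():
                lst.sort(key=lambda g: (g.interval.start, g.gene_id))
            self._trees = trees
            self._by_chrom = by_chrom

    def genes_overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[GeneModel]:
        """Genes whose span overlaps [start, end); optionally strand-matched.

        ``strand=None`` or ``'.'`` matches genes on either strand.
        """
        self._ensure_index()
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, end)]
        if strand in ("+", "-"):
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: g.gene_id)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        self._ensure_index()
        return list(self._by_chrom.get(chrom, []))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV (name, length in bp) -> ordered mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     dtype={"chrom": str, "size": int}, comment="#")
    if df["chrom"].duplicated().any():
        dup = df.loc[df["chrom"].duplicated(), "chrom"].iloc[0]
        raise AnnotationError(f"{path}: duplicate chromosome {dup}")
    return dict(zip(df["chrom"], df["size"]))


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def _merge_union(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals: merge overlapping or touching pieces."""
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def read_annotation(path, sizes_path) -> GenomeAnnotation:
    """Read a GTF (exon features with gene_id attributes) plus a chrom-size TSV.

    Each gene becomes one :class:`GeneModel` whose exons are the union of all
    its exon records and whose interval is the union span.  GTF's 1-based
    inclusive coordinates are converted to internal 0-based half-open ones.
    Malformed lines raise :class:`GtfParseError` naming the line number;
    exons beyond chromosome bounds raise :class:`AnnotationError`.
    """
    sizes = read_chrom_sizes(sizes_path)
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GtfParseError(path, lineno,
                                    "expected 9 tab-separated columns")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GtfParseError(path, lineno, str(exc)) from exc
            if feat.featuretype != "exon":
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
            except (KeyError, IndexError):
                raise GtfParseError(path, lineno, "exon lacks gene_id attribute")
            if feat.start is None or feat.end is None or feat.start > feat.end:
                raise GtfParseError(path, lineno, "invalid exon coordinates")
            start0, end = feat.start - 1, feat.end  # 1-based inclusive -> half-open
            if feat.seqid not in sizes:
                raise AnnotationError(
                    f"{path}: line {lineno}: chromosome {feat.seqid} not in size table"
                )
            if start0 < 0 or end > sizes[feat.seqid]:
                raise AnnotationError(
                    f"{path}: line {lineno}: exon outside chromosome bounds"
                )
            rec = per_gene.setdefault(
                gene_id, {"chrom": feat.seqid, "strand": feat.strand or ".",
                          "exons": [], "biotype": "protein_coding"}
            )
            if rec["chrom"] != feat.seqid:
                raise AnnotationError(f"gene {gene_id}: exons on multiple chromosomes")
            if (feat.strand or ".") != rec["strand"]:
                raise AnnotationError(f"gene {gene_id}: exons on multiple strands")
            if "gene_biotype" in feat.attributes:
                rec["biotype"] = feat.attributes["gene_biotype"][0]
            rec["exons"].append((start0, end))
    genes = []
    for gene_id, rec in per_gene.items():
        merged = _merge_union(rec["exons"])
        exons = tuple(
            GenomicInterval(rec["chrom"], s, e, rec["strand"]) for s, e in merged
        )
        interval = GenomicInterval(
            rec["chrom"], merged[0][0], merged[-1][1], rec["strand"]
        )
        genes.append(GeneModel(gene_id, interval, exons, biotype=rec["biotype"]))
    return GenomeAnnotation(sizes, genes)


def write_annotation(annotation: GenomeAnnotation, path, sizes_path=None) -> None:
    """Write exon features as GTF (1-based inclusive), deterministically ordered."""
    with open(path, "w") as fh:
        for g in sorted(
            annotation, key=lambda g: (g.chrom, g.interval.start, g.gene_id)
        ):
            for ex in g.exons:
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1"; '
                    f'gene_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\teleanor_scan\texon\t{ex.start + 1}\t{ex.end}"
                    f"\t.\t{g.strand}\t.\t{attrs}\n"
                )
    if sizes_path is not None:
        write_chrom_sizes(annotation.chrom_sizes, sizes_path)


def read_bed6(path) -> pd.DataFrame:
    """BED6 -> DataFrame with columns chrom, start, end, name, score, strand."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=BED6_COLUMNS, comment="#",
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLUMNS)
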