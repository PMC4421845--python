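"""Fixed-width window grids and read counting (the 100-bp window track).

A read is assigned by its midpoint to every window containing that
midpoint.  Under the default non-overlapping tiling (step = width) each
read on a known chromosome therefore contributes exactly one count, and
column sums equal library sizes minus skipped reads — the property the
median-of-ratios normalisation downstream relies on.  Overlapping windows
(step < width) are supported but produce statistically dependent rows and
are logged as such.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import GenomeAnnotation, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

STRAND_MODES = ("stranded_same", "unstranded")


class GridConfigError(ValueError):
    pass


@dataclass(frozen=True)
class WindowGrid:
    """Per-chromosome tiling of fixed-width windows.

    Windows start at every multiple of ``step`` below the chromosome length
    (floor((L - 1) / step) + 1 of them); the last window is truncated at the
    chromosome end.  For non-overlapping tiling (step = width) this equals
    ceil(L / width) windows.
    """

    width: int
    step: int
    chrom_sizes: tuple[tuple[str, int], ...]
    strand_mode: str = "stranded_same"

    def __post_init__(self):
        if self.width < 1:
            raise GridConfigError("window width must be >= 1")
        if not (1 <= self.step <= self.width):
            raise GridConfigError(
                "step must satisfy 1 <= step <= width (a larger step would "
                "leave gaps and drop reads)"
            )
        if self.strand_mode not in STRAND_MODES:
            raise GridConfigError(f"unknown strand mode {self.strand_mode!r}")
        if self.step < self.width:
            logger.warning(
                "overlapping windows (step %d < width %d): counts of adjacent "
                "windows share reads and are not independent in DE testing",
                self.step, self.width,
            )

    def n_windows(self, length: int) -> int:
        return max(length - 1, 0) // self.step + 1

    def windows_for(self, chrom: str, length: int) -> pd.DataFrame:
        n = self.n_windows(length)
        starts = np.arange(n, dtype=np.int64) * self.step
        ends = np.minimum(starts + self.width, length)
        return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})

    def features(self) -> pd.DataFrame:
        """All windows in grid order; duplicated per strand in stranded mode."""
        per_chrom = [self.windows_for(c, L) for c, L in self.chrom_sizes]
        base = pd.concat(per_chrom, ignore_index=True)
        if self.strand_mode == "unstranded":
            base["strand"] = "."
            return base
        plus = base.copy()
        plus["strand"] = "+"
        minus = base.copy()
        minus["strand"] = "-"
        return pd.concat([plus, minus], ignore_index=True)


def make_grid(
    annotation: GenomeAnnotation,
    width: int = 100,
    step: int | None = None,
    strand_mode: str = "stranded_same",
) -> WindowGrid:
    """Grid over the annotation's chromosomes; default 100-bp tiling."""
    return WindowGrid(
        width=width,
        step=width if step is None else step,
        chrom_sizes=tuple(annotation.chrom_sizes.items()),
        strand_mode=strand_mode,
    )


@dataclass
class WindowCountMatrix:
    """Integer read counts per window (rows) per sample (columns).

    ``features`` carries chrom/start/end/strand per row, aligned with
    ``counts``.  ``totals`` records total reads per sample (counted +
    skipped); ``skipped`` the reads on chromosomes unknown to the grid.
    """

    features: pd.DataFrame
    counts: np.ndarray
    samples: list[str]
    totals: pd.Series
    skipped: pd.Series

    def __post_init__(self):
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError("counts shape does not match features/samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        df = self.features.reset_index(drop=True).copy()
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = pd.DataFrame({
            "sample": self.samples,
            "total_reads": [int(self.totals[s]) for s in self.samples],
            "skipped_reads": [int(self.skipped[s]) for s in self.samples],
        })
        meta.to_csv(str(path) + ".totals", sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WindowCountMatrix":
        df = pd.read_csv(path, sep="\t")
        feat_cols = ["chrom", "start", "end", "strand"]
        samples = [c for c in df.columns if c not in feat_cols]
        counts = df[samples].to_numpy(dtype=np.int64)
        try:
            meta = pd.read_csv(str(path) + ".totals", sep="\t").set_index("sample")
            totals = meta["total_reads"]
            skipped = meta["skipped_reads"]
        except FileNotFoundError:
            totals = pd.Series(counts.sum(axis=0), index=samples)
            skipped = pd.Series(0, index=samples)
        return cls(df[feat_cols], counts, samples,
                   totals.astype(int), skipped.astype(int))


def _window_hits(midpoints: np.ndarray, grid: WindowGrid, n: int):
    """(window index, read index) pairs for every window containing each midpoint."""
    w, s = grid.width, grid.step
    max_per = math.ceil(w / s)
    idx_list, read_list = [], []
    base = midpoints // s
    for d in range(max_per):
        k = base - d
        ok = (k >= 0) & (k < n) & (midpoints < k * s + w)
        idx_list.append(k[ok])
        read_list.append(np.nonzero(ok)[0])
    return np.concatenate(idx_list), np.concatenate(read_list)


def count_reads(
    reads: Mapping[str, pd.DataFrame],
    grid: WindowGrid,
) -> WindowCountMatrix:
    """Count reads into the grid, sample by sample.

    Assignment is by read midpoint ``floor((start + end) / 2)``.  In
    ``stranded_same`` mode counting is done separately per strand and the
    feature table carries one row per (window, strand).  Reads on unknown
    chromosomes are skipped with a warning and tallied per sample.
    """
    features = grid.features()
    samples = list(reads)
    chrom_sizes = dict(grid.chrom_sizes)
    # flat offsets of each chromosome's window block within one strand block
    offsets: dict[str, int] = {}
    off = 0
    for chrom, L in grid.chrom_sizes:
        offsets[chrom] = off
        off += grid.n_windows(L)
    block = off  # windows per strand block
    stranded = grid.strand_mode == "stranded_same"
    n_rows = len(features)
    counts = np.zeros((n_rows, len(samples)), dtype=np.int64)
    totals, skipped = {}, {}
    for j, sample in enumerate(samples):
        df = reads[sample]
        totals[sample] = len(df)
        known = df["chrom"].map(chrom_sizes.__contains__) if len(df) else \
            pd.Series(dtype=bool)
        n_skip = int((~known).sum()) if len(df) else 0
        if n_skip:
            logger.warning(
                "sample %s: skipping %d reads on chromosomes unknown to the grid",
                sample, n_skip,
            )
        skipped[sample] = n_skip
        if len(df) == 0:
            continue
        sub = df[known]
        mid = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        col = np.zeros(n_rows, dtype=np.int64)
        for chrom, chrom_df_idx in sub.groupby("chrom", sort=False).indices.items():
            L = chrom_sizes[chrom]
            nwin = grid.n_windows(L)
            m = mid[chrom_df_idx]
            widx, ridx = _window_hits(m, grid, nwin)
            if stranded:
                strands = sub["strand"].to_numpy()[chrom_df_idx][ridx]
                flat = offsets[chrom] + widx + np.where(strands == "-", block, 0)
            else:
                flat = offsets[chrom] + widx
            col += np.bincount(flat, minlength=n_rows)
        counts[:, j] = col
    return WindowCountMatrix(
        features=features,
        counts=counts,
        samples=samples,
        totals=pd.Series(totals),
        skipped=pd.Series(skipped),
    )


def count_gene_reads(
    reads: Mapping[str, pd.DataFrame],
    annotation: GenomeAnnotation,
    stranded: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene read counts over each gene's exon union (the mRNA signal).

    A read counts towards a gene when its midpoint falls in one of the
    gene's exons (strand-matched when ``stranded``).  Returns the gene x
    sample count table and the exonic length per gene.

    Uses a sorted-boundary search; exons of distinct genes must not overlap
    on the same strand (true for annotations produced by this package's
    simulator and for the flattened models the reader builds in practice).
    """
    # flatten exons per (chrom, strand)
    gene_ids = sorted(annotation.genes)
    exon_tab: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for gi, gene_id in enumerate(gene_ids):
        g = annotation.gene(gene_id)
        key = (g.chrom, g.strand)
        for ex in g.exons:
            exon_tab.setdefault(key, []).append((ex.start, ex.end, gi))
    lookup: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for key, ivs in exon_tab.items():
        ivs.sort()
        starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
        owner = np.array([o for _, _, o in ivs], dtype=np.int64)
        if (ends[:-1] > starts[1:]).any():
            raise ValueError(
                "overlapping exons of distinct genes on one strand are not "
                "supported by gene-level counting"
            )
        lookup[key] = (starts, ends, owner)

    samples = list(reads)
    counts = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        df = reads[sample]
        if len(df) == 0:
            continue
        mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        chroms = df["chrom"].to_numpy()
        strands = df["strand"].to_numpy()
        for key, (starts, ends, owner) in lookup.items():
            chrom, strand = key
            sel = chroms == chrom
            if stranded:
                sel &= strands == strand
            m = mid[sel]
            if m.size == 0:
                continue
            pos = np.searchsorted(starts, m, side="right") - 1
            ok = (pos >= 0) & (m < ends[np.maximum(pos, 0)])
            hits = owner[pos[ok]]
            counts[:, j] += np.bincount(hits, minlength=len(gene_ids))
    table = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                         columns=samples)
    exonic = pd.Series(
        {gid: annotation.gene(gid).exonic_length for gid in gene_ids},
        name="exonic_length",
    )
    return table, exonic
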