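"""Region-to-gene assignment, the four-way screen, domains and length sums."""

import numpy as np
import pandas as pd
import pytest

from eleanor_scan.coreg_screen import (
    assign_region_to_gene,
    assign_regions,
    call_domain,
    coregulation_screen,
    four_way_venn,
    length_summary,
    load_reference_gene_table,
    reference_length_summary,
)
from eleanor_scan.genome_model import GenomeAnnotation, GenomicInterval

from conftest import make_gene


@pytest.fixture
def flank_annotation():
    """A + strand gene at 100,000 and a - strand gene at 300,000-310,000."""
    plus = make_gene("plus", "chr1", [(100_000, 101_000),
                                      (119_000, 120_000)])
    minus = make_gene("minus", "chr1", [(300_000, 301_000),
                                        (309_000, 310_000)], strand="-")
    return GenomeAnnotation({"chr1": 500_000}, [plus, minus])


def region(chrom, start, end, strand=".", cls="intergene", host=None,
           direction="up"):
    return pd.Series({"chrom": chrom, "start": start, "end": end,
                      "strand": strand, "region_class": cls,
                      "host_gene": host, "direction": direction})


class TestAssignment:
    def test_genic_region_keeps_host(self, flank_annotation):
        r = region("chr1", 105_000, 105_500, "+", cls="intron", host="plus")
        assert assign_region_to_gene(r, flank_annotation) == "plus"

    def test_upstream_40kb_within_flank(self, flank_annotation):
        r = region("chr1", 58_000, 60_000, "+")
        assert assign_region_to_gene(r, flank_annotation,
                                     upstream_flank=50_000) == "plus"

    def test_upstream_60kb_outside_flank(self, flank_annotation):
        r = region("chr1", 38_000, 40_000, "+")
        assert assign_region_to_gene(r, flank_annotation,
                                     upstream_flank=50_000) is None

    def test_minus_strand_upstream_lies_rightwards(self, flank_annotation):
        r = region("chr1", 350_000, 352_000, "-")
        assert assign_region_to_gene(r, flank_annotation) == "minus"
        # the same coordinates on + strand have no downstream TSS in reach
        r = region("chr1", 350_000, 352_000, "+")
        assert assign_region_to_gene(r, flank_annotation) is None

    def test_region_downstream_of_gene_not_assigned(self, flank_annotation):
        r = region("chr1", 130_000, 131_000, "+")
        assert assign_region_to_gene(r, flank_annotation) is None


class TestVenn:
    def test_identical_sets_collapse_to_full_pattern(self):
        s = {"a", "b", "c"}
        out = four_way_venn({"w": set(s), "x": set(s), "y": set(s),
                             "z": set(s)})
        assert len(out) == 1
        assert out.iloc[0]["pattern"] == "1111"
        assert out.iloc[0]["count"] == 3

    def test_disjoint_singletons(self):
        out = four_way_venn({"w": {"a"}, "x": {"b"}, "y": {"c"}, "z": {"d"}})
        assert len(out) == 4
        assert set(out["count"]) == {1}
        assert set(out["pattern"]) == {"1000", "0100", "0010", "0001"}

    def test_matches_per_element_tabulation(self):
        rng = np.random.default_rng(43)
        universe = [f"g{i}" for i in range(60)]
        sets = {n: {g for g in universe if rng.random() < p}
                for n, p in zip("wxyz", [0.3, 0.5, 0.2, 0.4])}
        out = four_way_venn(sets)
        # exhaustive per-element membership tabulation
        expect = {}
        for g in set().union(*sets.values()):
            key = "".join("1" if g in sets[n] else "0" for n in sets)
            expect[key] = expect.get(key, 0) + 1
        assert dict(zip(out["pattern"], out["count"])) == expect
        assert out["count"].sum() == len(set().union(*sets.values()))


class TestCallDomain:
    gene = GenomicInterval("chr1", 100_000, 300_000, "+")

    def regions(self, ivs):
        return pd.DataFrame([{"chrom": "chr1", "start": s, "end": e}
                             for s, e in ivs])

    def test_intronic_region_gives_gene_span(self):
        dom = call_domain(self.gene, self.regions([(150_000, 160_000)]))
        assert (dom.start, dom.end) == (100_000, 300_000)

    def test_upstream_region_bridged_with_wide_gap(self):
        regions = self.regions([(58_000, 60_000)])  # 40 kb upstream
        dom10 = call_domain(self.gene, regions, bridge_gap=10_000)
        assert (dom10.start, dom10.end) == (100_000, 300_000)
        dom50 = call_domain(self.gene, regions, bridge_gap=50_000)
        assert (dom50.start, dom50.end) == (58_000, 300_000)

    def test_regions_chain_through_each_other(self):
        regions = self.regions([(330_000, 340_000), (345_000, 350_000),
                                (500_000, 501_000)])
        dom = call_domain(self.gene, regions, bridge_gap=30_000)
        # first two chain to the gene; the 150-kb jump is never bridged
        assert (dom.start, dom.end) == (100_000, 350_000)


class TestScreen:
    def annotation(self):
        genes = [
            make_gene("long", "chr1", [(100_000, 101_000),
                                       (399_000, 400_000)]),
            make_gene("short", "chr1", [(600_000, 601_000),
                                        (616_000, 617_000)]),
            make_gene("quiet", "chr1", [(800_000, 801_000),
                                        (815_000, 816_000)]),
        ]
        return GenomeAnnotation({"chr1": 1_000_000}, genes)

    def gene_table(self, labels):
        return pd.DataFrame(
            {"label": pd.Series(labels)},
            index=pd.Index(list(labels), name="gene_id"),
        )

    def nc_table(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                           "direction", "region_class",
                                           "host_gene", "gene_id"])

    def test_empty_inputs_give_empty_output(self):
        out = coregulation_screen(
            self.gene_table({}), self.gene_table({}),
            self.nc_table([]), self.nc_table([]), self.annotation())
        assert out.empty

    def test_verdicts_match_set_logic(self):
        mrna_ab = self.gene_table({"long": "up", "short": "up", "quiet": "ns"})
        mrna_bc = self.gene_table({"long": "down", "short": "down",
                                   "quiet": "ns"})
        nc_ab = self.nc_table([
            ("chr1", 150_000, 152_000, "+", "up", "intron", "long", "long"),
        ])
        nc_bc = self.nc_table([
            ("chr1", 200_000, 201_000, "+", "down", "intron", "long", "long"),
        ])
        out = coregulation_screen(mrna_ab, mrna_bc, nc_ab, nc_bc,
                                  self.annotation()).set_index("gene_id")
        assert out.loc["long", "verdict"] == "coordinated"
        assert out.loc["short", "verdict"] == "mrna_only"
        assert out.loc["quiet", "verdict"] == "other"
        # brute-force check of the verdict definition over all genes
        up_ab = set(mrna_ab.index[mrna_ab["label"] == "up"])
        dn_bc = set(mrna_bc.index[mrna_bc["label"] == "down"])
        ncu = set(nc_ab.loc[nc_ab["direction"] == "up", "gene_id"])
        ncd = set(nc_bc.loc[nc_bc["direction"] == "down", "gene_id"])
        for gid, row in out.iterrows():
            in_all = gid in up_ab & dn_bc & ncu & ncd
            in_mrna = gid in up_ab & dn_bc
            expect = ("coordinated" if in_all
                      else "mrna_only" if in_mrna else "other")
            assert row["verdict"] == expect

    def test_output_sorted_by_length_descending(self):
        mrna_ab = self.gene_table({"long": "up", "short": "up"})
        mrna_bc = self.gene_table({"long": "down", "short": "down"})
        out = coregulation_screen(mrna_ab, mrna_bc, self.nc_table([]),
                                  self.nc_table([]), self.annotation())
        assert list(out["length_bp"]) == sorted(out["length_bp"],
                                                reverse=True)

    def test_order_of_inputs_is_irrelevant(self):
        mrna_ab = self.gene_table({"long": "up", "short": "up"})
        mrna_bc = self.gene_table({"long": "down", "short": "down"})
        nc = self.nc_table([
            ("chr1", 150_000, 152_000, "+", "up", "intron", "long", "long"),
            ("chr1", 610_000, 611_000, "+", "up", "intron", "short", "short"),
        ])
        a = coregulation_screen(mrna_ab, mrna_bc, nc, self.nc_table([]),
                                self.annotation())
        b = coregulation_screen(mrna_ab.iloc[::-1], mrna_bc, nc.iloc[::-1],
                                self.nc_table([]), self.annotation())
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_gene_id_raises_with_name(self):
        with pytest.raises(KeyError, match="ghost"):
            coregulation_screen(self.gene_table({"ghost": "up"}),
                                self.gene_table({}), self.nc_table([]),
                                self.nc_table([]), self.annotation())

    def test_coordinated_implies_mrna_pattern(self):
        """The coordination verdict refines, never contradicts, the mRNA
        up-then-down requirement."""
        mrna_ab = self.gene_table({"long": "up", "short": "ns"})
        mrna_bc = self.gene_table({"long": "down", "short": "down"})
        nc = self.nc_table([
            ("chr1", 150_000, 152_000, "+", "up", "intron", "long", "long"),
            ("chr1", 610_000, 611_000, "+", "up", "intron", "short", "short"),
        ])
        nc_dn = self.nc_table([
            ("chr1", 150_500, 151_000, "+", "down", "intron", "long", "long"),
            ("chr1", 610_000, 611_000, "+", "down", "intron", "short",
             "short"),
        ])
        out = coregulation_screen(mrna_ab, mrna_bc, nc, nc_dn,
                                  self.annotation()).set_index("gene_id")
        assert out.loc["long", "verdict"] == "coordinated"
        assert out.loc["short", "verdict"] == "other"  # mRNA gate failed


class TestLengthSummary:
    def test_single_gene_mean_is_its_length(self):
        out = length_summary({"g": [12_345]})
        assert out.iloc[0]["mean_length_bp"] == 12_345

    def test_empty_group_reports_nan_mean(self):
        out = length_summary({"none": []})
        assert out.iloc[0]["n"] == 0
        assert np.isnan(out.iloc[0]["mean_length_bp"])

    def test_rounding_is_half_up(self):
        assert length_summary({"g": [1, 2]}).iloc[0]["mean_length_bp"] == 2

    def test_reference_table_group_means(self):
        """The published 13-gene groups: the mRNA-only group averages
        16,839 bp; the coordinated group's listed lengths average 280,065 bp
        (the widely quoted 280,142 bp figure is not the arithmetic mean of
        the listed column)."""
        out = reference_length_summary().set_index("group")
        assert out.loc["non_coordinated", "n"] == 13
        assert out.loc["non_coordinated", "mean_length_bp"] == 16_839
        assert out.loc["coordinated", "n"] == 13
        assert out.loc["coordinated", "mean_length_bp"] == 280_065

    def test_reference_table_contents(self):
        tab = load_reference_gene_table()
        assert len(tab) == 26
        assert tab.set_index("gene").loc["ESR1", "length_bp"] == 412_778
        assert tab.set_index("gene").loc["ERBB2", "length_bp"] == 40_523
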