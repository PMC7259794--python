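"""Enhancer/silencer classification, concordance, and summary counts."""

import pytest

from raretarget import (DirectionalGeneSet, GenomicInterval, MarkKind,
                        RegulationDirection, build_candidates,
                        classify_element, mark_concordance, scan_rares,
                        summarize)
from raretarget.assignment import PeakGeneLink
from raretarget.core import PipelineConfig
from raretarget.differential import SignificantPeakSet
from raretarget.io_formats import DiffPeakRecord


class TestClassifyElement:
    def test_direction_determines_class(self):
        assert classify_element(RegulationDirection.RA_ACTIVATED) == "enhancer"
        assert classify_element(RegulationDirection.RA_REPRESSED) == "silencer"


class TestMarkConcordance:
    @pytest.mark.parametrize("mark, fc, direction, expected", [
        (MarkKind.H3K27ME3, 1.02, RegulationDirection.RA_ACTIVATED, True),
        (MarkKind.H3K27AC, 0.53, RegulationDirection.RA_REPRESSED, True),
        (MarkKind.H3K27AC, 0.53, RegulationDirection.RA_ACTIVATED, False),
        (MarkKind.H3K27AC, -1.23, RegulationDirection.RA_ACTIVATED, True),
        (MarkKind.H3K27ME3, -0.49, RegulationDirection.RA_REPRESSED, True),
        (MarkKind.H3K27ME3, -0.49, RegulationDirection.RA_ACTIVATED, False),
        (MarkKind.H3K27AC, -1.23, RegulationDirection.RA_REPRESSED, False),
        (MarkKind.H3K27ME3, 1.02, RegulationDirection.RA_REPRESSED, False),
    ])
    def test_sign_table(self, mark, fc, direction, expected):
        assert mark_concordance(mark, fc, direction) is expected


class TestPublishedTable:
    """The 27 published peak/gene rows behave as the table's structure implies."""

    def test_all_rows_concordant(self, table1_rows):
        for row in table1_rows:
            direction = (RegulationDirection.RA_ACTIVATED if row.rna_log2fc < 0
                         else RegulationDirection.RA_REPRESSED)
            assert mark_concordance(row.mark, row.peak_log2fc, direction), \
                f"{row.gene_id} {row.mark.value} {row.peak_log2fc}"

    def test_silencer_supporting_rows(self, table1_rows):
        silencer_genes = set()
        enhancer_genes = set()
        for row in table1_rows:
            direction = (RegulationDirection.RA_ACTIVATED if row.rna_log2fc < 0
                         else RegulationDirection.RA_REPRESSED)
            if classify_element(direction) == "silencer":
                silencer_genes.add(row.gene_id)
            else:
                enhancer_genes.add(row.gene_id)
        assert silencer_genes == {"Fgf8", "Fst", "Cdx2", "Spry4"}
        assert not (silencer_genes & enhancer_genes)


def sig_peak(mark, fc, start, chrom="chr1", length=1000):
    return DiffPeakRecord(interval=GenomicInterval(chrom, start, start + length),
                          mark=mark, log2fc=fc, pvalue=1e-6, bh_p=1e-6)


def link(peak, gene, link_type="nearest"):
    return PeakGeneLink(peak=peak, gene_id=gene, link_type=link_type,
                        distance=100)


class TestBuildCandidates:
    def setup_method(self):
        self.p_ac = sig_peak(MarkKind.H3K27AC, -1.0, 1000)
        self.p_me = sig_peak(MarkKind.H3K27ME3, 1.0, 5000)
        self.peaksets = [SignificantPeakSet(MarkKind.H3K27AC, [self.p_ac]),
                         SignificantPeakSet(MarkKind.H3K27ME3, [self.p_me])]
        self.de = DirectionalGeneSet(activated={"geneA"}, repressed={"geneR"})

    def test_both_marks_merge_into_one_target(self):
        targets = build_candidates(
            self.peaksets, self.de,
            [link(self.p_ac, "geneA"), link(self.p_me, "geneA")])
        assert len(targets) == 1
        t = targets[0]
        assert t.direction is RegulationDirection.RA_ACTIVATED
        assert {l.peak.mark for l in t.links} == set(MarkKind)
        assert all(l.concordant for l in t.links)

    def test_non_de_nearest_gene_contributes_nothing(self):
        targets = build_candidates(self.peaksets, self.de,
                                   [link(self.p_ac, "boring")])
        assert targets == []

    def test_de_gene_without_peak_is_no_target(self):
        targets = build_candidates(self.peaksets, self.de,
                                   [link(self.p_ac, "geneA")])
        assert [t.gene_id for t in targets] == ["geneA"]  # geneR absent

    def test_rares_attached_only_inside_linked_peak(self):
        genome_piece = "GGGTCAGCAGTTCA"  # perfect DR2
        inside = scan_rares(genome_piece,
                            origin=GenomicInterval("chr1", 1200, 1214), tol=0)
        outside = scan_rares(genome_piece,
                             origin=GenomicInterval("chr1", 9000, 9014), tol=0)
        rares = {self.p_ac.interval.region_string(): inside + outside}
        targets = build_candidates(self.peaksets, self.de,
                                   [link(self.p_ac, "geneA")], rares)
        spans = {r.match.interval.start for r in targets[0].rares}
        assert spans and all(1000 <= s < 2000 for s in spans)
        assert all(r.element_class == "enhancer" for r in targets[0].rares)

    def test_strict_containment_drops_edge_overlaps(self):
        edge = scan_rares("GGGTCAGCAGTTCA",
                          origin=GenomicInterval("chr1", 1995, 2009), tol=0)
        rares = {self.p_ac.interval.region_string(): edge}
        loose = build_candidates(self.peaksets, self.de,
                                 [link(self.p_ac, "geneA")], rares)
        assert loose[0].rares  # >=1 bp overlap is enough by default
        strict = build_candidates(self.peaksets, self.de,
                                  [link(self.p_ac, "geneA")], rares,
                                  PipelineConfig(strict_containment=True))
        assert not strict[0].rares

    def test_silencer_class_for_repressed_gene(self):
        hits = scan_rares("GGGTCAGCAGTTCA",
                          origin=GenomicInterval("chr1", 5200, 5214), tol=0)
        rares = {self.p_me.interval.region_string(): hits}
        targets = build_candidates(self.peaksets, self.de,
                                   [link(self.p_me, "geneR")], rares)
        assert targets[0].direction is RegulationDirection.RA_REPRESSED
        assert all(r.element_class == "silencer" for r in targets[0].rares)


class TestSummarize:
    def _targets(self, k27ac_genes, k27me3_genes):
        out = []
        all_genes = set(k27ac_genes) | set(k27me3_genes)
        for i, g in enumerate(sorted(all_genes)):
            links = []
            if g in k27ac_genes:
                links.append(link(sig_peak(MarkKind.H3K27AC, -1, 1000 + i * 10_000), g))
            if g in k27me3_genes:
                links.append(link(sig_peak(MarkKind.H3K27ME3, 1, 5000 + i * 10_000), g))
            t = build_candidates(
                [SignificantPeakSet(MarkKind.H3K27AC, [l.peak for l in links
                                                       if l.peak.mark is MarkKind.H3K27AC]),
                 SignificantPeakSet(MarkKind.H3K27ME3, [l.peak for l in links
                                                        if l.peak.mark is MarkKind.H3K27ME3])],
                DirectionalGeneSet(activated=all_genes), links)
            out.extend(t)
        return out

    def test_published_set_union(self):
        # 63 acetylation-linked and 41 trimethylation-linked genes sharing 11
        shared = {"Rarb", "Dhrs3", "Fgf8", "Cdx2", "Fst", "Meis1", "Meis2",
                  "Nr2f2", "Foxp4", "Ptprs", "Zfhx4"}
        k27ac = shared | {f"ac{i:02d}" for i in range(52)}
        k27me3 = shared | {f"me{i:02d}" for i in range(30)}
        assert (len(k27ac), len(k27me3)) == (63, 41)
        counts = summarize(self._targets(k27ac, k27me3))
        assert counts.n_genes_k27ac == 63
        assert counts.n_genes_k27me3 == 41
        assert counts.n_genes_union == 93

    @pytest.mark.parametrize("a, b, expected", [
        ({"g1", "g2"}, {"g3", "g4", "g5"}, 5),
        ({"g1", "g2"}, {"g1", "g2"}, 2),
    ])
    def test_small_unions(self, a, b, expected):
        assert summarize(self._targets(a, b)).n_genes_union == expected

    def test_idempotent_and_order_invariant(self):
        targets = self._targets({"a", "b"}, {"b", "c"})
        once = summarize(targets)
        assert summarize(targets) == once
        assert summarize(targets[::-1]) == once
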