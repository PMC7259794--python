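"""Direct-repeat consensus scanning: worked examples, strand symmetry,
brute-force equivalence, and the published element classifications."""

import numpy as np
import pytest

from raretarget import (GenomicInterval, HalfSiteConsensus, best_match,
                        classify_printed_rare, count_halfsite_mismatches,
                        scan_peak, scan_rares)
from raretarget.scanner import reverse_complement

from _oracles import brute_force_drs


class TestHalfSiteMismatches:
    @pytest.mark.parametrize("six_mer, expected", [
        ("GGGTCA", 0),
        ("AGTTCA", 0),   # A at 1 and T at 3 conform to R/K degeneracy
        ("GGGTTA", 1),   # T at position 5 violates the C
        ("NNNNNN", 6),   # N never matches
        ("gggtca", 0),   # case-insensitive
    ])
    def test_examples(self, six_mer, expected):
        assert count_halfsite_mismatches(six_mer) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            count_halfsite_mismatches("GGGTC")

    def test_bad_consensus_rejected(self):
        with pytest.raises(ValueError):
            HalfSiteConsensus("RGKTCAX")


class TestScanRares:
    def test_perfect_dr5(self):
        hits = scan_rares("GGTTCACCGAAAGTTCA", tol=1)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        h = plus[0]
        assert (h.motif_type, h.spacer, h.mismatches) == ("DR5", 5, 0)
        assert h.interval.length == 17
        assert h.matched_sequence == "GGTTCACCGAAAGTTCA"

    def test_dr1_with_one_mismatch(self):
        hits = [h for h in scan_rares("GTGTCAAAGTTCA", tol=1) if h.strand == "+"]
        assert len(hits) == 1
        assert (hits[0].motif_type, hits[0].mismatches) == ("DR1", 1)

    def test_strand_symmetry(self):
        seq = "GGGTCAGAAGGTCA"
        fwd = scan_rares(seq, tol=1)
        rev = scan_rares(reverse_complement(seq), tol=1)
        assert {(h.motif_type, h.mismatches, h.interval.length) for h in fwd} \
            == {(h.motif_type, h.mismatches, h.interval.length) for h in rev}
        assert any(h.motif_type == "DR2" and h.strand == "-"
                   for h in scan_rares(reverse_complement(seq), tol=1))

    def test_homopolymer_yields_nothing(self):
        assert scan_rares("A" * 17, tol=1) == []

    def test_empty_sequence(self):
        assert scan_rares("", tol=2) == []

    def test_origin_offsets_coordinates(self):
        origin = GenomicInterval("chr6", 52153425, 52153442)
        hits = scan_rares("GGTTCACCGAAAGTTCA", origin=origin, tol=1)
        h = best_match(hits)
        assert h.interval.region_string() == "chr6:52153426-52153442"

    def test_origin_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scan_rares("ACGT", origin=GenomicInterval("chr1", 0, 5))

    def test_tolerance_monotone(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            prev = set()
            for tol in (0, 1, 2):
                cur = {(h.interval.start, h.interval.end, h.motif_type, h.strand)
                       for h in scan_rares(seq, tol=tol)}
                assert prev <= cur
                prev = cur

    @pytest.mark.parametrize("tol", [0, 1, 2])
    def test_matches_brute_force(self, tol):
        rng = np.random.default_rng(100 + tol)
        for _ in range(400):
            length = int(rng.integers(13, 41))
            seq = "".join(rng.choice(list("ACGTN"), size=length,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            ours = {(h.interval.start, h.interval.end, h.motif_type,
                     h.strand, h.mismatches) for h in scan_rares(seq, tol=tol)}
            assert ours == brute_force_drs(seq, tol)


class TestScanPeak:
    genome = {"chr1": "A" * 50 + "GGGTCAGCAGTTCA" + "A" * 50}

    def test_planted_dr2_found_at_genomic_coordinates(self):
        peak = GenomicInterval("chr1", 40, 110)
        hits = [h for h in scan_peak(peak, self.genome, tol=0)
                if h.strand == "+"]
        assert len(hits) == 1
        assert (hits[0].interval.start, hits[0].interval.end) == (50, 64)
        assert hits[0].motif_type == "DR2"

    def test_tolerance_gates_single_mismatch_site(self):
        genome = {"chr1": "C" * 20 + "GTGTCAAAGTTCA" + "C" * 20}
        peak = GenomicInterval("chr1", 0, 53)
        assert scan_peak(peak, genome, tol=0) == []
        assert len(scan_peak(peak, genome, tol=1)) == 1

    def test_peak_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            scan_peak(GenomicInterval("chr1", 100, 200), self.genome)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            scan_peak(GenomicInterval("chrX", 0, 10), self.genome)


class TestClassifyPrinted:
    @pytest.mark.parametrize("printed, expected", [
        ("GGTTCA CCGAA AGTTCA", ("DR5", 0)),
        ("GGGTGA C AGGTCA", ("DR1", 1)),
        ("GGGTCA GC AGTTCA", ("DR2", 0)),
    ])
    def test_examples(self, printed, expected):
        assert classify_printed_rare(printed) == expected

    def test_bad_spacer_length_rejected(self):
        with pytest.raises(ValueError, match="spacer"):
            classify_printed_rare("GGGTCA ACT AGGTCA")

    def test_all_published_rows_classified_as_printed(self, table2_rows):
        for row in table2_rows:
            motif_type, mm = classify_printed_rare(row.sequence)
            assert motif_type == row.motif_type, row.sequence
            assert mm <= 1, row.sequence


def test_best_match_prefers_fewest_mismatches_then_longest():
    # DR5 window also contains a shorter imperfect DR1 parse
    hits = scan_rares("GGTTCACCGAAAGTTCA", tol=2)
    best = best_match(hits)
    assert (best.motif_type, best.mismatches) == ("DR5", 0)
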