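"""Scan a DNA sequence for DR1/DR2/DR5 retinoic-acid response elements.

The scanner slides a direct-repeat template (two RGKTCA half-sites around
a 1/2/5-bp spacer) over both strands and reports every window within the
mismatch tolerance. The sequence below is the published element in the
Hoxa1 3'-noncoding region, whose deletion disrupts hindbrain patterning.
"""

from raretarget import best_match, scan_rares

sequence = "GGTTCACCGAAAGTTCA"

hits = scan_rares(sequence, tol=1)
print(f"{len(hits)} hit(s) in {sequence!r} at tolerance 1:")
for h in hits:
    print(f"  {h.motif_type} {h.strand} strand, spacer {h.spacer} bp, "
          f"{h.mismatches} mismatch(es): {h.matched_sequence}")

best = best_match(hits)
print(f"best call: {best.motif_type} with {best.mismatches} mismatches")
# The DR5 architecture (5-bp spacer) is the classic high-affinity RAR/RXR
# site; a 0-mismatch call means both half-sites match the consensus exactly.
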