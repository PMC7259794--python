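# Methods

## Coordinates

Internally everything is 0-based half-open (BED convention). Human-facing
region strings are 1-based inclusive UCSC style, so `chr6:52153426-52153442`
is internally `[52153425, 52153442)` and 17 bp long. Both the en-dash and
hyphen are accepted as range separators and commas are stripped, because
published coordinate tables print en-dashes. The midpoint of an interval is
`floor((start + end − 1) / 2)`: for even lengths the lower of the two
central positions, a deterministic tie-break.

## Differential filters

Genes and peaks arrive with externally computed fold changes and raw
p-values (the count-model test itself — DESeq2/edgeR territory — is out of
scope; those tools' outputs are this package's inputs). The filters are:

| quantity | threshold | default | note |
|---|---|---|---|
| expression \|log2FC\| | strict `>` | 0.85 | admits known targets near the boundary |
| FPKM, both genotypes | strict `>` | 0.5 | expressed in at least one state |
| H3K27ac \|log2FC\| | strict `>` | 0.51 | per-mark cutoff |
| H3K27me3 \|log2FC\| | strict `>` | 0.47 | per-mark cutoff |
| peak BH-adjusted p | `<` | 0.05 | per-mark adjustment family |

All comparisons are strict, so boundary ties are excluded. BH adjustment is
the classical step-up, `adj_(i) = min_{j≥i} p_(j)·n/j` capped at 1,
implemented vectorized and cross-checked in tests against both a scalar
textbook implementation and statsmodels. Adjustment is per mark: the two
marks were assayed as separate experiments and form separate
multiple-testing families. Records arriving with a `bh_p` column are
trusted as externally adjusted. An optional expression-level FDR filter
exists (`rna_bh_alpha`) but is off by default; the published gene filter
used only the fold-change and FPKM cutoffs.

## Peak→gene linkage

The primary link is the gene whose annotated TSS is nearest the peak
midpoint, with ties broken by lexicographically smaller gene symbol.
Midpoint-to-TSS is the convention of the common peak annotators; it is not
printed in most methods sections, so it is fixed here and configurable to
nearest-edge (`distance_anchor="edge"`). The distance is always
|midpoint − TSS|, including when the TSS lies inside the peak — one
convention, no special cases.

Distal regulation is rescued through TADs: each significant peak is
assigned to the single TAD containing its midpoint (boundary-spanning peaks
are never assigned to two TADs), and every *differentially expressed* gene
whose TSS lies in that TAD gains a `tad` link, excluding the gene already
linked as nearest. Gene-in-TAD membership is by TSS containment, not gene-
body overlap: the promoter is the regulatory anchor and this avoids double-
assigning boundary-spanning genes. Peaks outside every TAD stay
nearest-linked only, and their count is logged.

## Motif scanning

The scanner is consensus-based: the half-site pattern `RGKTCA` (R = A/G,
K = G/T), two half-sites around an unconstrained spacer of 1, 2, or 5 bp,
both strands, every offset. Mismatches are counted over the 12 half-site
positions only — spacer letters vary freely among published perfect-
consensus elements, so constraining them would be wrong. `N` never matches;
windows running off the sequence end are skipped. The default pattern is
`RGKTCA` rather than the literal `AGGTCA` because published perfect sites
include `GGGTCA`, `AGTTCA`, and `GGTTCA`; the pattern is configurable.

A position-weight-matrix scanner would be the natural alternative, but the
published evidence for each element is a printed consensus sequence and a
mismatch count, which the consensus scanner reproduces exactly (verified:
all 24 printed elements classify to their printed DR type within 1
mismatch). No PWM is printed, so one cannot be reconstructed faithfully.

Overlapping hits of different spacer classes are all reported — real loci
genuinely carry e.g. a DR1 parse inside a DR5 window — and `best_match`
deduplicates (fewest mismatches, then longest, then leftmost) when a single
call per locus is wanted. The match set at tolerance t is a subset of the
set at t+1 by construction; an independent brute-force enumerator confirms
scanner output exactly on randomized sequences in the test suite.

## Classification and integration

A candidate target is a gene passing the expression filter with ≥ 1 linked
significant peak. RAREs found in a linked peak are attached to the gene and
classed by the *gene's* direction — enhancer for RA-activated, silencer for
RA-repressed. The mark's own direction only sets a concordance flag: there
is a validated case of a silencer sitting in an H3K27ac-gain peak, so mark
direction must not veto. A RARE reached through peaks linked to genes of
opposite directions receives both classes, one per gene row, with a logged
warning. By default a RARE needs ≥ 1 bp overlap with the peak (edge cases
are documented in the source literature); `strict_containment=True`
requires the full window inside the peak.

## Conservation

Real conservation calls were made by manual genome-browser homology
inspection, which is not reproducible programmatically. The operational
definition here: a RARE is conserved in clade c iff the supplied
orthologous window for c contains a same-DR-type match within the
high-confidence tolerance (default 1 mismatch), on either strand. Windows
are an explicit per-clade FASTA input (record id `chrom:start-end:TYPE`);
computing them from whole-genome alignments is a non-goal. Alignment gaps
(`-`) are stripped before scanning. The tier is the most distal conserved
clade in the order rodent < human < bird < reptile < frog < fish, and a
distal match with missing intermediate clades still sets the distal tier
(tiers, not paths, are reported). The highly conserved set is tier ∈
{bird, reptile, frog, fish} with mismatches ≤ 1.

## Synthetic data

The generator emulates the statistical structure the integration assumes,
not the physics of sequencing:

- **Genome**: i.i.d. uniform ACGT, default 4 chromosomes × 4 Mb. No repeat
  structure or GC skew — the scanner is consensus-based, so composition
  affects only chance-hit rates, which the oracle tests cover directly.
- **Genes**: default 550, on a per-chromosome grid with ±2 kb jitter. Grid
  spacing (≈ 29 kb at defaults) exceeds twice the maximum peak-to-TSS
  offset, so each proximal peak's nearest TSS is its own gene's by
  construction; a feasibility check rejects densities where this fails.
- **TADs**: tile each chromosome evenly, 8 per chromosome.
- **True targets**: default 50, of which 30 % RA-repressed. Each gets one
  peak (mark chosen uniformly) within 10 kb of its TSS, or anywhere in its
  TAD for a 20 % distal fraction; peak |log2FC| ~ Normal(2.0, 0.3)
  truncated above the mark threshold, sign concordant; expression likewise
  truncated above the RNA threshold; raw p ~ U(0, 1e-4); FPKMs
  floor + LogNormal so both genotypes clear the floor. The effect location
  2.0 with sd 0.3 reproduces the magnitude range observed in real
  differential tables (expression roughly 0.9–5.4, marks 0.5–1.2).
- **Planted RAREs**: one per true peak, type uniform over DR1/DR2/DR5,
  mismatches 0 or 1 (70/30), written by substitution so coordinates never
  shift. Ortholog windows are the planted locus ±30 bp, copied verbatim for
  clades up to the element's randomly assigned tier and letter-shuffled
  beyond, giving nested conservation by construction.
- **Nulls**: 500 null genes and 200 null peaks with log2FC ~ Normal(0,
  0.2) and p ~ U(0, 1). A null gene must clear a ≈ 4σ fold-change cutoff
  *and* link to a significant peak to become a false positive, so expected
  false-positive counts at defaults are ≪ 1 per run.

Everything is reproducible from a single integer seed. What passing
recovery tests show: the plumbing is correct end-to-end — thresholds,
linkage, scanning, classing, and conservation tiers compose without loss
under the assumed signal/noise structure. What they do not show: robustness
to correlated nulls, peak-calling artifacts, mappability gaps, paralogous
motif clusters, or mis-annotated TSSs, none of which the generator models.

## Numerical and degenerate-input choices

- Empty p-value vectors return empty; p-values outside [0, 1] are an error.
- An empty sequence scans to an empty match list; a window shorter than the
  motif cannot be conserved.
- Nearest-gene on a chromosome with no genes returns an explicit
  `unassigned` link rather than raising.
- Candidate-table rows sort by (chrom, start, gene), making re-runs
  byte-identical; the run manifest records config, input checksums, and
  stage counts.

## Known limitations

- Consensus-with-mismatches is a coarser model than a PWM; borderline
  sites score identically whether the mismatch is conservative or not.
- DR0/DR3/DR4 spacers, liftover, chromosome-name aliasing, and GTF/GFF
  gene models are out of scope.
- The gene set reachable through TAD rescue depends entirely on the
  supplied TAD set; TAD boundaries from a different tissue are an
  approximation inherited from the input, not corrected here.
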