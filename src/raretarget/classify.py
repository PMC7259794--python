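"""Integration of peaks, gene links, and motif hits into candidate targets.

A candidate RA target gene is one with a passing expression change and at
least one significant peak linked to it (nearest-TSS or same-TAD). RAREs
found inside a linked peak are attached to the gene and classified by the
gene's regulation direction: elements near RA-activated genes are
candidate enhancers, elements near RA-repressed genes candidate
silencers. Mark directionality is recorded as a concordance flag, not a
veto — a repressed gene's element in an acetylation-gain peak is still a
silencer candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import (GenomicInterval, MarkKind, PipelineConfig,
                   RegulationDirection, interval_overlap)
from .assignment import PeakGeneLink
from .differential import DirectionalGeneSet, SignificantPeakSet
from .scanner import RareMatch

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifiedRare", "CandidateTarget", "SummaryCounts",
    "classify_element", "mark_concordance", "build_candidates", "summarize",
]


@dataclass
class ClassifiedRare:
    """A RARE attached to a candidate gene, with its element class and
    (once computed) conservation tier."""

    match: RareMatch
    element_class: str
    peak_region: str  # display string of the containing peak
    conserved_to: str | None = None


@dataclass
class CandidateTarget:
    gene_id: str
    direction: RegulationDirection
    links: list[PeakGeneLink] = field(default_factory=list)
    rares: list[ClassifiedRare] = field(default_factory=list)


@dataclass
class SummaryCounts:
    n_genes_k27ac: int
    n_genes_k27me3: int
    n_genes_union: int
    n_genes_with_rare: int
    n_rare_enhancers: int
    n_rare_silencers: int
    n_highly_conserved: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def classify_element(direction: RegulationDirection) -> str:
    """Element class from the linked gene's regulation direction."""
    return ("enhancer" if direction is RegulationDirection.RA_ACTIVATED
            else "silencer")


def mark_concordance(mark: MarkKind, peak_log2fc: float,
                     direction: RegulationDirection) -> bool:
    """Does the mark's direction of change agree with the gene's?

    For an RA-activated gene (expression falls in the knockout), loss of
    the activating mark (H3K27ac down) or gain of the repressive mark
    (H3K27me3 up) is concordant; mirrored for RA-repressed genes.
    """
    if direction is RegulationDirection.RA_ACTIVATED:
        return ((mark is MarkKind.H3K27AC and peak_log2fc < 0)
                or (mark is MarkKind.H3K27ME3 and peak_log2fc > 0))
    return ((mark is MarkKind.H3K27AC and peak_log2fc > 0)
            or (mark is MarkKind.H3K27ME3 and peak_log2fc < 0))


def _rare_in_peak(rare: RareMatch, peak_iv: GenomicInterval, strict: bool) -> bool:
    if strict:
        return (rare.interval.chrom == peak_iv.chrom
                and rare.interval.start >= peak_iv.start
                and rare.interval.end <= peak_iv.end)
    return interval_overlap(rare.interval, peak_iv) > 0


def build_candidates(
    peaksets: list[SignificantPeakSet],
    de: DirectionalGeneSet,
    links: list[PeakGeneLink],
    rares_by_peak: dict[str, list[RareMatch]] | None = None,
    cfg: PipelineConfig | None = None,
) -> list[CandidateTarget]:
    """Assemble one candidate target per gene with >=1 linked significant peak.

    ``links`` are the nearest/tad links produced for the significant
    peaks; only links whose gene passed the expression filter count.
    ``rares_by_peak`` maps a peak's region string to the motif hits found
    inside it; hits are attached to every target whose linked peak
    contains them (>=1 bp overlap, or full containment in strict mode).
    """
    cfg = cfg or PipelineConfig()
    rares_by_peak = rares_by_peak or {}
    significant_regions = {
        p.interval.region_string() for ps in peaksets for p in ps.peaks
    }

    by_gene: dict[str, CandidateTarget] = {}
    for link in links:
        if link.gene_id is None or link.gene_id not in de:
            continue
        if link.peak.interval.region_string() not in significant_regions:
            continue
        direction = (RegulationDirection.RA_ACTIVATED
                     if link.gene_id in de.activated
                     else RegulationDirection.RA_REPRESSED)
        target = by_gene.setdefault(
            link.gene_id, CandidateTarget(gene_id=link.gene_id, direction=direction))
        key = (link.peak.interval.region_string(), link.peak.mark)
        if any((l.peak.interval.region_string(), l.peak.mark) == key
               and l.link_type == link.link_type for l in target.links):
            continue  # (peak, gene) pair at most once per link type
        link.concordant = mark_concordance(link.peak.mark, link.peak.log2fc,
                                           direction)
        target.links.append(link)

        element_class = classify_element(direction)
        peak_region = link.peak.interval.region_string()
        for match in rares_by_peak.get(peak_region, []):
            if not _rare_in_peak(match, link.peak.interval, cfg.strict_containment):
                continue
            if any(r.match == match and r.peak_region == peak_region
                   for r in target.rares):
                continue
            target.rares.append(ClassifiedRare(
                match=match, element_class=element_class, peak_region=peak_region))

    # a RARE shared by peaks linked to opposite-direction genes gets both
    # classes, one per target row; flag it, the situation is ambiguous
    seen: dict[tuple, str] = {}
    for t in by_gene.values():
        for r in t.rares:
            key = (r.match.interval, r.match.motif_type)
            if key in seen and seen[key] != r.element_class:
                logger.warning(
                    "RARE %s classified as both enhancer and silencer via "
                    "different genes", r.match.interval.region_string())
            seen[key] = r.element_class

    return sorted(by_gene.values(), key=lambda t: t.gene_id)


def summarize(targets: list[CandidateTarget]) -> SummaryCounts:
    """Headline counts with set-union semantics over gene symbols."""
    k27ac = {t.gene_id for t in targets
             if any(l.peak.mark is MarkKind.H3K27AC for l in t.links)}
    k27me3 = {t.gene_id for t in targets
              if any(l.peak.mark is MarkKind.H3K27ME3 for l in t.links)}
    with_rare = {t.gene_id for t in targets if t.rares}
    enhancers = sum(1 for t in targets for r in t.rares
                    if r.element_class == "enhancer")
    silencers = sum(1 for t in targets for r in t.rares
                    if r.element_class == "silencer")
    conserved = sum(1 for t in targets for r in t.rares
                    if r.conserved_to not in (None, "", "none"))
    return SummaryCounts(
        n_genes_k27ac=len(k27ac), n_genes_k27me3=len(k27me3),
        n_genes_union=len(k27ac | k27me3), n_genes_with_rare=len(with_rare),
        n_rare_enhancers=enhancers, n_rare_silencers=silencers,
        n_highly_conserved=conserved)
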