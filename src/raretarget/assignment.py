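"""Linking differential peaks to genes.

Primary linkage is the nearest annotated transcription start site (TSS),
measured from the peak midpoint (the convention of standard peak
annotators; configurable to nearest peak edge). Secondary linkage rescues
distal regulation: every differentially expressed gene whose TSS lies in
the same topologically associating domain (TAD) as the peak is linked,
except the gene already captured as nearest.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .core import GenomicInterval, PipelineConfig, midpoint
from .differential import DirectionalGeneSet
from .io_formats import DiffPeakRecord, GeneModel, TadDomain

__all__ = ["PeakGeneLink", "nearest_gene", "assign_tad", "tad_links"]


@dataclass
class PeakGeneLink:
    peak: DiffPeakRecord
    gene_id: str | None
    link_type: str  # "nearest" | "tad" | "unassigned"
    distance: int | None
    tad_id: str | None = None
    concordant: bool | None = None


def _anchor_distance(peak_iv: GenomicInterval, tss: int, anchor: str) -> int:
    if anchor == "edge":
        if peak_iv.contains_point(tss):
            return 0
        return min(abs(peak_iv.start - tss), abs(peak_iv.end - 1 - tss))
    return abs(midpoint(peak_iv) - tss)


def nearest_gene(peak: DiffPeakRecord, genes: list[GeneModel],
                 cfg: PipelineConfig | None = None) -> PeakGeneLink:
    """Link a peak to the gene minimizing |anchor - TSS|.

    Ties are broken by lexicographically smaller gene_id. A chromosome
    with no genes yields an explicit unassigned link.
    """
    cfg = cfg or PipelineConfig()
    candidates = [g for g in genes if g.interval.chrom == peak.interval.chrom]
    if not candidates:
        return PeakGeneLink(peak=peak, gene_id=None, link_type="unassigned",
                            distance=None)
    best = min(candidates, key=lambda g: (
        _anchor_distance(peak.interval, g.tss, cfg.distance_anchor), g.gene_id))
    return PeakGeneLink(
        peak=peak, gene_id=best.gene_id, link_type="nearest",
        distance=_anchor_distance(peak.interval, best.tss, cfg.distance_anchor))


def assign_tad(peak: DiffPeakRecord, tads: list[TadDomain]) -> TadDomain | None:
    """The TAD containing the peak midpoint (half-open), or None.

    Peaks spanning a boundary belong to the midpoint's TAD only.
    """
    pos = midpoint(peak.interval)
    chrom_tads = sorted((t for t in tads if t.interval.chrom == peak.interval.chrom),
                        key=lambda t: t.interval.start)
    starts = [t.interval.start for t in chrom_tads]
    i = bisect.bisect_right(starts, pos) - 1
    if i >= 0 and chrom_tads[i].interval.contains_point(pos):
        return chrom_tads[i]
    return None


def tad_links(peak: DiffPeakRecord, tad: TadDomain, genes: list[GeneModel],
              de: DirectionalGeneSet,
              nearest_gene_id: str | None = None) -> list[PeakGeneLink]:
    """Same-TAD rescue links: one per differentially expressed gene with
    its TSS in the TAD, excluding the peak's nearest gene.

    More than one regulated gene per TAD is expected and supported.
    """
    links = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.interval.chrom != tad.interval.chrom:
            continue
        if not tad.interval.contains_point(g.tss):
            continue
        if g.gene_id == nearest_gene_id or g.gene_id not in de:
            continue
        links.append(PeakGeneLink(
            peak=peak, gene_id=g.gene_id, link_type="tad",
            distance=abs(midpoint(peak.interval) - g.tss), tad_id=tad.tad_id))
    return links
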