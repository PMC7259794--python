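"""End-to-end orchestration: differential filters -> peak-gene linking ->
motif scanning -> enhancer/silencer classification -> conservation tiers.

Runs entirely in memory on the domain objects the readers produce; the
CLI wraps this with file I/O and a run manifest. Stage-by-stage record
counts are logged to standard error.
"""

from __future__ import annotations

import logging

from .core import MarkKind, PipelineConfig
from .assignment import assign_tad, nearest_gene, tad_links
from .classify import CandidateTarget, build_candidates, summarize
from .conservation import conservation_flags, conservation_tier
from .differential import filter_de_genes, filter_diff_peaks
from .scanner import scan_peak

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def run_pipeline(
    expression,
    peaks_by_mark: dict[MarkKind, list],
    genes,
    genome: dict[str, str],
    tads=None,
    orthologs: dict[str, dict[str, str]] | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[list[CandidateTarget], dict]:
    """Run every stage and return (candidate targets, summary counts).

    ``tads`` may be None, in which case distal same-TAD rescue is skipped
    and peaks are nearest-linked only. ``orthologs`` maps clade ->
    {"chrom:start-end:TYPE": window}; when absent, conservation tiers are
    left unset.
    """
    cfg = cfg or PipelineConfig()
    de = filter_de_genes(expression, cfg)
    logger.info("expression: %d activated, %d repressed of %d genes",
                len(de.activated), len(de.repressed), len(expression))

    peaksets = []
    for mark, records in peaks_by_mark.items():
        if not records:
            continue
        ps = filter_diff_peaks(records, cfg)
        logger.info("%s: %d of %d peaks significant", mark.value,
                    len(ps.peaks), len(records))
        peaksets.append(ps)

    if tads is None:
        logger.info("no TADs supplied: TAD rescue disabled, nearest-only linkage")

    links = []
    n_outside_tads = 0
    for ps in peaksets:
        for peak in ps.peaks:
            near = nearest_gene(peak, genes, cfg)
            links.append(near)
            if tads:
                tad = assign_tad(peak, tads)
                if tad is None:
                    n_outside_tads += 1
                else:
                    links.extend(tad_links(peak, tad, genes, de,
                                           nearest_gene_id=near.gene_id))
    if tads and n_outside_tads:
        logger.info("%d significant peaks fall outside every TAD "
                    "(nearest-linked only)", n_outside_tads)

    rares_by_peak = {}
    for ps in peaksets:
        for peak in ps.peaks:
            region = peak.interval.region_string()
            if region not in rares_by_peak:
                rares_by_peak[region] = scan_peak(
                    peak, genome, tol=cfg.scan_mismatch_tol, cfg=cfg)
    logger.info("scanned %d significant peaks: %d motif hits",
                len(rares_by_peak), sum(map(len, rares_by_peak.values())))

    targets = build_candidates(peaksets, de, links, rares_by_peak, cfg)

    if orthologs is not None:
        for t in targets:
            for r in t.rares:
                key = (f"{r.match.interval.region_string()}:"
                       f"{r.match.motif_type}")
                windows = {clade: clade_map[key]
                           for clade, clade_map in orthologs.items()
                           if key in clade_map}
                flags = conservation_flags(r.match, windows, cfg)
                r.conserved_to = conservation_tier(flags, cfg)

    summary = summarize(targets).as_dict()
    logger.info("candidates: %d genes (%d with >=1 RARE)",
                summary["n_genes_union"], summary["n_genes_with_rare"])
    return targets, summary
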