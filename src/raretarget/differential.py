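"""Significance and effect-size filters for expression and peak tables.

Fold-change cutoffs are strict inequalities on |log2FC| (knockout vs
wild type); peaks additionally require a Benjamini-Hochberg adjusted
p-value below alpha. BH adjustment is applied per mark: the two histone
marks were assayed and compared as separate experiments, so their peak
families form separate multiple-testing universes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MarkKind, PipelineConfig
from .io_formats import DiffExprRecord, DiffPeakRecord

__all__ = [
    "DirectionalGeneSet", "SignificantPeakSet",
    "bh_adjust", "filter_de_genes", "filter_diff_peaks",
]


@dataclass
class DirectionalGeneSet:
    """Genes partitioned by RA regulation direction.

    ``activated``: expression falls in the RA-deficient knockout
    (log2FC below -threshold); ``repressed``: expression rises.
    """

    activated: set[str] = field(default_factory=set)
    repressed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        both = self.activated & self.repressed
        if both:
            raise ValueError(f"genes in both directions: {sorted(both)}")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.activated or gene_id in self.repressed

    @property
    def all_genes(self) -> set[str]:
        return self.activated | self.repressed


@dataclass
class SignificantPeakSet:
    mark: MarkKind
    peaks: list[DiffPeakRecord] = field(default_factory=list)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min_{j >= rank(i)} p_(j) * n / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(n, dtype=float)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def filter_de_genes(records: list[DiffExprRecord],
                    cfg: PipelineConfig | None = None) -> DirectionalGeneSet:
    """Apply the expression filters: strict |log2FC| cutoff and an FPKM
    floor in both genotypes.

    An optional expression-level FDR filter (``cfg.rna_bh_alpha``) is off
    by default; when enabled it requires a raw p-value column and applies
    BH across all genes in the table.
    """
    cfg = cfg or PipelineConfig()
    passing_fdr = None
    if cfg.rna_bh_alpha is not None:
        pvals = [r.pvalue for r in records]
        if any(p is None for p in pvals):
            raise ValueError("rna_bh_alpha set but expression table lacks p-values")
        adj = bh_adjust(pvals)
        passing_fdr = {r.gene_id for r, a in zip(records, adj) if a < cfg.rna_bh_alpha}

    out = DirectionalGeneSet()
    for rec in records:
        if not (rec.fpkm_wt > cfg.fpkm_min and rec.fpkm_ko > cfg.fpkm_min):
            continue
        if passing_fdr is not None and rec.gene_id not in passing_fdr:
            continue
        if rec.log2fc < -cfg.rna_abs_log2fc_min:
            out.activated.add(rec.gene_id)
        elif rec.log2fc > cfg.rna_abs_log2fc_min:
            out.repressed.add(rec.gene_id)
    return out


def filter_diff_peaks(records: list[DiffPeakRecord],
                      cfg: PipelineConfig | None = None) -> SignificantPeakSet:
    """Retain peaks with strict |log2FC| above the mark threshold and
    BH-adjusted p below alpha.

    All records must carry the same mark (one multiple-testing family per
    call). Records lacking ``bh_p`` have it computed here over the whole
    input; records arriving with ``bh_p`` are trusted as externally
    adjusted.
    """
    cfg = cfg or PipelineConfig()
    if not records:
        raise ValueError("no peak records supplied")
    marks = {r.mark for r in records}
    if len(marks) > 1:
        raise ValueError(f"mixed marks in one call: {sorted(m.value for m in marks)}")
    mark = marks.pop()
    threshold = cfg.mark_threshold(mark)

    if any(r.bh_p is None for r in records):
        adj = bh_adjust([r.pvalue for r in records])
        for rec, a in zip(records, adj):
            rec.bh_p = float(a)

    kept = []
    for rec in records:
        if abs(rec.log2fc) > threshold and rec.bh_p < cfg.bh_alpha:
            rec.direction = "increased_in_KO" if rec.log2fc > 0 else "decreased_in_KO"
            kept.append(rec)
    return SignificantPeakSet(mark=mark, peaks=kept)
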