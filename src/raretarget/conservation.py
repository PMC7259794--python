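"""Cross-species conservation tiering of RAREs.

"Conserved in clade X" is operationalized as: the supplied orthologous
sequence window for that clade contains a same-type direct-repeat match
within the high-confidence mismatch tolerance, on either strand. The
conservation tier of an element is the most distal conserved clade in
the order rodent < human < bird < reptile < frog < fish; a distal match
with missing intermediate clades still sets the distal tier. Elements
conserved beyond mammals (bird or further) with at most one half-site
mismatch form the highly conserved set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import BEYOND_MAMMAL_CLADES, PipelineConfig
from .scanner import classify_printed_rare, scan_rares

logger = logging.getLogger(__name__)

__all__ = [
    "CladeFlags", "rare_conserved_in", "conservation_flags",
    "conservation_tier", "filter_highly_conserved", "fixture_conservation_summary",
]


@dataclass
class CladeFlags:
    flags: dict[str, bool] = field(default_factory=dict)

    def __getitem__(self, clade: str) -> bool:
        return self.flags[clade]


def rare_conserved_in(window: str, motif_type: str, tol: int,
                      cfg: PipelineConfig | None = None) -> bool:
    """True iff the window holds a same-type DR match within tolerance.

    Alignment gap characters ('-') are stripped before scanning; a window
    that is all gaps is not conserved.
    """
    seq = window.replace("-", "").upper()
    if len(seq) < 13:  # shortest motif window (DR1)
        return False
    return any(m.motif_type == motif_type and m.mismatches <= tol
               for m in scan_rares(seq, tol=tol, cfg=cfg))


def conservation_flags(rare, windows: dict[str, str],
                       cfg: PipelineConfig | None = None) -> CladeFlags:
    """Per-clade conservation of one RARE given its ortholog windows.

    ``rare`` needs a ``motif_type`` attribute; a clade with no window is
    not conserved.
    """
    cfg = cfg or PipelineConfig()
    flags = {}
    for clade in cfg.clade_order:
        window = windows.get(clade)
        flags[clade] = (window is not None
                        and rare_conserved_in(window, rare.motif_type,
                                              cfg.high_conf_mismatch_tol, cfg))
    return CladeFlags(flags=flags)


def conservation_tier(flags: CladeFlags, cfg: PipelineConfig | None = None) -> str:
    """Most distal conserved clade, or 'none'."""
    cfg = cfg or PipelineConfig()
    tier = "none"
    gaps = False
    for clade in cfg.clade_order:
        if flags.flags.get(clade, False):
            if tier != "none" and gaps:
                logger.debug("distal tier %s set despite missing intermediate clade",
                             clade)
            tier = clade
        elif tier != "none":
            gaps = True
    return tier


def _is_highly_conserved(tier: str, mismatches: int,
                         cfg: PipelineConfig) -> bool:
    return tier in BEYOND_MAMMAL_CLADES and mismatches <= cfg.high_conf_mismatch_tol


def filter_highly_conserved(targets, cfg: PipelineConfig | None = None):
    """Highly conserved RAREs across candidate targets, plus their gene set.

    Retains classified RAREs whose conservation tier is beyond mammals
    (bird, reptile, frog, or fish) and whose scan mismatch count is within
    the high-confidence tolerance; the gene set unions the owning genes.
    """
    cfg = cfg or PipelineConfig()
    retained = []
    genes: set[str] = set()
    for t in targets:
        for r in t.rares:
            tier = r.conserved_to or "none"
            if _is_highly_conserved(tier, r.match.mismatches, cfg):
                retained.append(r)
                genes.add(t.gene_id)
    return retained, genes


def fixture_conservation_summary(rows, cfg: PipelineConfig | None = None):
    """Apply the highly-conserved filter to published fixture rows.

    Each row carries printed per-clade flags, a printed spaced sequence,
    and nearest/same-TAD gene columns. Returns (retained rows, distinct
    gene set, max mismatch count over retained rows).
    """
    cfg = cfg or PipelineConfig()
    retained = []
    genes: set[str] = set()
    max_mm = 0
    for row in rows:
        tier = conservation_tier(CladeFlags(flags=row.conserved), cfg)
        motif_type, mm = classify_printed_rare(row.sequence)
        if motif_type != row.motif_type:
            raise ValueError(
                f"fixture row {row.interval.region_string()}: printed spacer "
                f"implies {motif_type}, row says {row.motif_type}")
        if _is_highly_conserved(tier, mm, cfg):
            retained.append(row)
            genes.add(row.nearest_gene)
            genes.update(row.tad_genes)
            max_mm = max(max_mm, mm)
    return retained, genes, max_mm
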