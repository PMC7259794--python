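"""Consensus scanner for DR1/DR2/DR5 retinoic-acid response elements.

A RARE is a direct repeat of the nuclear-receptor half-site (consensus
``RGKTCA``; R = A/G, K = G/T) separated by a 1, 2, or 5 bp spacer. The
scanner slides every (offset, spacer, strand) window over a sequence,
counts mismatches against the half-site consensus over the 12 half-site
positions only — spacer letters are unconstrained — and reports every
window within the mismatch tolerance. ``N`` never matches. Minus-strand
hits are reported in plus-strand coordinates with ``strand='-'``.

Overlapping hits of different spacer classes are all reported; consumers
wanting one call per locus deduplicate with :func:`best_match` (fewest
mismatches, then longest span, then leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GenomicInterval, PipelineConfig

__all__ = [
    "HalfSiteConsensus",
    "RareMatch",
    "SPACER_TO_TYPE",
    "TYPE_TO_SPACER",
    "count_halfsite_mismatches",
    "scan_rares",
    "scan_peak",
    "classify_printed_rare",
    "best_match",
    "reverse_complement",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

SPACER_TO_TYPE = {1: "DR1", 2: "DR2", 5: "DR5"}
TYPE_TO_SPACER = {v: k for k, v in SPACER_TO_TYPE.items()}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HalfSiteConsensus:
    """A 6-letter IUPAC half-site pattern."""

    pattern: str = "RGKTCA"

    def __post_init__(self) -> None:
        if len(self.pattern) != 6:
            raise ValueError("half-site consensus must be 6 letters")
        bad = [c for c in self.pattern.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"non-IUPAC letters in consensus: {bad}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    @property
    def allowed(self) -> tuple[frozenset, ...]:
        return tuple(frozenset(IUPAC[c]) for c in self.pattern)


@dataclass(frozen=True)
class RareMatch:
    """One direct-repeat hit: half-site + spacer + half-site."""

    interval: GenomicInterval
    motif_type: str
    strand: str
    spacer: int
    mismatches: int
    matched_sequence: str

    def __post_init__(self) -> None:
        if TYPE_TO_SPACER.get(self.motif_type) != self.spacer:
            raise ValueError(
                f"motif type {self.motif_type} inconsistent with spacer {self.spacer}"
            )
        if self.interval.length != 12 + self.spacer:
            raise ValueError("interval length must equal 12 + spacer")


def count_halfsite_mismatches(six_mer: str, consensus: HalfSiteConsensus | None = None) -> int:
    """Number of the 6 positions violating the IUPAC class; N never matches."""
    if consensus is None:
        consensus = HalfSiteConsensus()
    six_mer = six_mer.upper()
    if len(six_mer) != 6:
        raise ValueError(f"expected a 6-mer, got {six_mer!r}")
    return sum(base not in allowed
               for base, allowed in zip(six_mer, consensus.allowed))


def _scan_one_strand(seq: str, tol: int, consensus: HalfSiteConsensus):
    """Yield (offset, spacer, mismatches, window) for plus-strand windows."""
    allowed = consensus.allowed
    n = len(seq)
    for spacer in (1, 2, 5):
        width = 12 + spacer
        second = 6 + spacer
        for off in range(n - width + 1):
            mm = 0
            for i in range(6):
                if seq[off + i] not in allowed[i]:
                    mm += 1
                    if mm > tol:
                        break
                if seq[off + second + i] not in allowed[i]:
                    mm += 1
                    if mm > tol:
                        break
            else:
                yield off, spacer, mm, seq[off:off + width]


def scan_rares(
    seq: str,
    origin: GenomicInterval | None = None,
    tol: int = 2,
    cfg: PipelineConfig | None = None,
) -> list[RareMatch]:
    """Scan both strands of ``seq`` for DR1/DR2/DR5 elements.

    Parameters
    ----------
    seq
        DNA over ACGTN (case-insensitive).
    origin
        Genomic interval the sequence was taken from; match coordinates are
        reported inside it. When omitted, matches are on a pseudo-contig
        spanning the sequence.
    tol
        Maximum total half-site mismatches.
    cfg
        Supplies the half-site consensus when given.
    """
    seq = seq.upper()
    if not seq:
        return []
    consensus = HalfSiteConsensus(cfg.halfsite_consensus if cfg else "RGKTCA")
    if origin is not None and origin.length != len(seq):
        raise ValueError("origin length must equal sequence length")
    chrom = origin.chrom if origin is not None else "seq"
    base = origin.start if origin is not None else 0

    matches: list[RareMatch] = []
    for off, spacer, mm, window in _scan_one_strand(seq, tol, consensus):
        matches.append(RareMatch(
            interval=GenomicInterval(chrom, base + off, base + off + 12 + spacer),
            motif_type=SPACER_TO_TYPE[spacer], strand="+",
            spacer=spacer, mismatches=mm, matched_sequence=window,
        ))
    rc = reverse_complement(seq)
    n = len(seq)
    for off, spacer, mm, window in _scan_one_strand(rc, tol, consensus):
        width = 12 + spacer
        fwd_off = n - off - width
        matches.append(RareMatch(
            interval=GenomicInterval(chrom, base + fwd_off, base + fwd_off + width),
            motif_type=SPACER_TO_TYPE[spacer], strand="-",
            spacer=spacer, mismatches=mm, matched_sequence=window,
        ))
    matches.sort(key=lambda m: (m.interval.start, m.motif_type, m.strand))
    return matches


def scan_peak(peak, genome: dict[str, str], tol: int = 2,
              cfg: PipelineConfig | None = None) -> list[RareMatch]:
    """Scan the genomic sequence under a differential peak.

    ``peak`` is anything with an ``interval`` attribute (or an interval
    itself); output coordinates are genomic.
    """
    iv: GenomicInterval = getattr(peak, "interval", peak)
    if iv.chrom not in genome:
        raise KeyError(f"chromosome {iv.chrom!r} not in genome")
    chrom_seq = genome[iv.chrom]
    if iv.end > len(chrom_seq):
        raise ValueError(
            f"peak {iv.region_string()} extends beyond end of {iv.chrom} "
            f"({len(chrom_seq)} bp)"
        )
    return scan_rares(chrom_seq[iv.start:iv.end], origin=iv, tol=tol, cfg=cfg)


def classify_printed_rare(printed: str,
                          consensus: HalfSiteConsensus | None = None) -> tuple[str, int]:
    """Classify a space-separated printed element ``HALF SPACER HALF``.

    Returns the DR type implied by the spacer length and the total
    half-site mismatch count.
    """
    parts = printed.split()
    if len(parts) != 3:
        raise ValueError(f"expected 'HALF SPACER HALF', got {printed!r}")
    half1, spacer, half2 = parts
    if len(spacer) not in SPACER_TO_TYPE:
        raise ValueError(f"spacer length {len(spacer)} is not 1, 2, or 5")
    mm = (count_halfsite_mismatches(half1, consensus)
          + count_halfsite_mismatches(half2, consensus))
    return SPACER_TO_TYPE[len(spacer)], mm


def best_match(matches: list[RareMatch]) -> RareMatch | None:
    """Single best call: fewest mismatches, then longest, then leftmost."""
    if not matches:
        return None
    return min(matches, key=lambda m: (m.mismatches, -m.interval.length,
                                       m.interval.start, m.strand))
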