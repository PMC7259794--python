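"""Coordinate conventions, interval arithmetic, and shared domain types.

All internal coordinates are 0-based half-open (BED convention). Human-facing
region strings ("chr6:52153426-52153442", UCSC style) are 1-based inclusive;
:func:`parse_region` and :meth:`GenomicInterval.region_string` convert between
the two. Both the en-dash and the ASCII hyphen are accepted as range
separators, and commas inside positions are stripped.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace

__all__ = [
    "GenomicInterval",
    "MarkKind",
    "RegulationDirection",
    "PipelineConfig",
    "parse_region",
    "interval_overlap",
    "midpoint",
]


class MarkKind(str, enum.Enum):
    """The two histone marks profiled: acetylation (activating) and
    trimethylation (repressive) of H3 lysine 27."""

    H3K27AC = "H3K27ac"
    H3K27ME3 = "H3K27me3"


class RegulationDirection(str, enum.Enum):
    """Direction of retinoic-acid regulation inferred from expression.

    Fold changes are knockout-over-wild-type, so a gene *activated* by RA
    loses expression in the RA-deficient knockout (negative log2FC) and a
    gene *repressed* by RA gains expression (positive log2FC).
    """

    RA_ACTIVATED = "RA_activated"
    RA_REPRESSED = "RA_repressed"


_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:[{self.start},{self.end}): "
                "start must be < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def region_string(self) -> str:
        """1-based inclusive display form, e.g. ``chr1:101-200``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def with_strand(self, strand: str) -> "GenomicInterval":
        return replace(self, strand=strand)


_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>[\d,]+)[–-](?P<end>[\d,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive region string into an interval.

    Accepts en-dash or hyphen separators and commas in positions, as
    printed in UCSC-style coordinate tables.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"unparseable region string: {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    return GenomicInterval(m.group("chrom"), start - 1, end)


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length in bp under half-open semantics; 0 when disjoint or on
    different chromosomes. Abutting intervals do not overlap."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def midpoint(a: GenomicInterval) -> int:
    """0-based midpoint, floor((start + end - 1) / 2).

    For even lengths this is the lower of the two central positions, a
    deterministic tie-break used for nearest-TSS distances and TAD
    containment.
    """
    return (a.start + a.end - 1) // 2


#: Clades ordered proximal-to-distal from mouse; fish is most distal.
DEFAULT_CLADE_ORDER = ("rodent", "human", "bird", "reptile", "frog", "fish")

#: Clades beyond mammals; conservation to any of these marks a RARE as
#: highly conserved.
BEYOND_MAMMAL_CLADES = frozenset({"bird", "reptile", "frog", "fish"})


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across the pipeline.

    Defaults are the study's published cutoffs: expression |log2FC| > 0.85
    with FPKM > 0.5 in both genotypes; mark |log2FC| > 0.51 (H3K27ac) or
    0.47 (H3K27me3) with BH-adjusted p < 0.05; motif scanning tolerates up
    to 2 half-site mismatches, and the high-confidence conservation tier
    tolerates at most 1.
    """

    rna_abs_log2fc_min: float = 0.85
    fpkm_min: float = 0.5
    k27ac_abs_log2fc_min: float = 0.51
    k27me3_abs_log2fc_min: float = 0.47
    bh_alpha: float = 0.05
    rna_bh_alpha: float | None = None  # optional expression FDR filter, off by default
    scan_mismatch_tol: int = 2
    high_conf_mismatch_tol: int = 1
    halfsite_consensus: str = "RGKTCA"
    clade_order: tuple[str, ...] = DEFAULT_CLADE_ORDER
    strict_containment: bool = False  # require RAREs fully inside peaks
    distance_anchor: str = "midpoint"  # or "edge"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rna_abs_log2fc_min", "fpkm_min", "k27ac_abs_log2fc_min",
                     "k27me3_abs_log2fc_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.bh_alpha < 1.0):
            raise ValueError("bh_alpha must lie in (0, 1)")
        if not (0 <= self.high_conf_mismatch_tol <= self.scan_mismatch_tol):
            raise ValueError(
                "need 0 <= high_conf_mismatch_tol <= scan_mismatch_tol"
            )
        if self.distance_anchor not in ("midpoint", "edge"):
            raise ValueError("distance_anchor must be 'midpoint' or 'edge'")

    def mark_threshold(self, mark: MarkKind) -> float:
        return (self.k27ac_abs_log2fc_min if mark is MarkKind.H3K27AC
                else self.k27me3_abs_log2fc_min)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs = dict(mapping)
        if "clade_order" in kwargs:
            kwargs["clade_order"] = tuple(kwargs["clade_order"])
        return cls(**kwargs)
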