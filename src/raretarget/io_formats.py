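"""Readers and writers for every file the pipeline touches.

Peak, expression, gene, and TAD tables are TSV/BED with 0-based half-open
coordinates; region strings in human-facing output are 1-based inclusive.
Readers validate rather than coerce: malformed rows raise with the
offending line number. Packaged fixtures transcribe the published tables
of worked examples (27 peak/gene rows; 24 highly conserved elements).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

from .core import GenomicInterval, MarkKind, parse_region

__all__ = [
    "DiffPeakRecord", "DiffExprRecord", "GeneModel", "TadDomain",
    "Table1Row", "Table2Row",
    "read_diff_peaks", "read_diff_expr", "read_genome_fasta",
    "read_gene_bed", "read_tad_bed", "read_ortholog_fasta",
    "load_table1_fixture", "load_table2_fixture",
    "write_candidate_table", "read_candidate_table",
]


@dataclass
class DiffPeakRecord:
    """A differential histone-mark peak (log2FC is KO over WT)."""

    interval: GenomicInterval
    mark: MarkKind
    log2fc: float
    pvalue: float
    bh_p: float | None = None
    direction: str | None = None  # set by the differential filter

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")
        if self.bh_p is not None and not (0.0 <= self.bh_p <= 1.0):
            raise ValueError(f"adjusted p-value {self.bh_p} outside [0, 1]")


@dataclass
class DiffExprRecord:
    """Differential expression of one gene (log2FC is KO over WT)."""

    gene_id: str
    log2fc: float
    fpkm_wt: float
    fpkm_ko: float
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.fpkm_wt < 0 or self.fpkm_ko < 0:
            raise ValueError(f"negative FPKM for {self.gene_id}")


@dataclass
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    strand: str

    @property
    def tss(self) -> int:
        """Transcription start: interval start on +, end-1 on -."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass
class TadDomain:
    tad_id: str
    interval: GenomicInterval


def _open_rows(path):
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        yield from ((i, row) for i, row in enumerate(reader, start=1))


def _header_index(header: list[str], required: list[str], path) -> dict[str, int]:
    idx = {name: i for i, name in enumerate(header)}
    for col in required:
        if col not in idx:
            raise ValueError(f"{path}: missing required column {col!r}")
    return idx


def _as_float(value: str, path, lineno: int, col: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(
            f"{path} line {lineno}: non-numeric {col} value {value!r}"
        ) from None


def read_diff_peaks(path, mark: MarkKind) -> list[DiffPeakRecord]:
    """Read a differential-peak TSV (chrom, start, end, log2fc, pvalue[, bh_p])."""
    rows = _open_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty file") from None
    idx = _header_index(header, ["chrom", "start", "end", "log2fc", "pvalue"], path)
    has_bh = "bh_p" in idx
    records = []
    for lineno, row in rows:
        if not row or not any(row):
            continue
        try:
            interval = GenomicInterval(row[idx["chrom"]],
                                       int(row[idx["start"]]), int(row[idx["end"]]))
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from None
        bh = None
        if has_bh and row[idx["bh_p"]] not in ("", "NA"):
            bh = _as_float(row[idx["bh_p"]], path, lineno, "bh_p")
        records.append(DiffPeakRecord(
            interval=interval, mark=mark,
            log2fc=_as_float(row[idx["log2fc"]], path, lineno, "log2fc"),
            pvalue=_as_float(row[idx["pvalue"]], path, lineno, "pvalue"),
            bh_p=bh,
        ))
    return records


def read_diff_expr(path) -> list[DiffExprRecord]:
    """Read an expression TSV (gene_id, log2fc, fpkm_wt, fpkm_ko[, pvalue])."""
    rows = _open_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty file") from None
    idx = _header_index(header, ["gene_id", "log2fc", "fpkm_wt", "fpkm_ko"], path)
    has_p = "pvalue" in idx
    seen: set[str] = set()
    records = []
    for lineno, row in rows:
        if not row or not any(row):
            continue
        gene = row[idx["gene_id"]]
        if gene in seen:
            raise ValueError(f"{path} line {lineno}: duplicate gene_id {gene!r}")
        seen.add(gene)
        records.append(DiffExprRecord(
            gene_id=gene,
            log2fc=_as_float(row[idx["log2fc"]], path, lineno, "log2fc"),
            fpkm_wt=_as_float(row[idx["fpkm_wt"]], path, lineno, "fpkm_wt"),
            fpkm_ko=_as_float(row[idx["fpkm_ko"]], path, lineno, "fpkm_ko"),
            pvalue=_as_float(row[idx["pvalue"]], path, lineno, "pvalue") if has_p else None,
        ))
    return records


def read_genome_fasta(path) -> dict[str, str]:
    """Load a FASTA into {name: uppercase sequence}; names cut at whitespace."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"{path}: duplicate record name {record.id!r}")
        genome[record.id] = str(record.seq).upper()
    if not genome:
        raise ValueError(f"{path}: no FASTA records found")
    return genome


read_ortholog_fasta = read_genome_fasta  # same format; record ids are RARE keys


def read_gene_bed(path) -> list[GeneModel]:
    """Read genes from BED6 (chrom, start, end, gene_id, score, strand)."""
    genes = []
    seen: set[str] = set()
    for lineno, row in _open_rows(path):
        if not row or row[0].startswith(("#", "track", "browser")):
            continue
        if len(row) < 6 or row[5] not in ("+", "-"):
            raise ValueError(f"{path} line {lineno}: gene BED needs 6 columns "
                             "with strand '+' or '-'")
        if row[3] in seen:
            raise ValueError(f"{path} line {lineno}: duplicate gene_id {row[3]!r}")
        seen.add(row[3])
        try:
            iv = GenomicInterval(row[0], int(row[1]), int(row[2]), row[5])
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from None
        genes.append(GeneModel(gene_id=row[3], interval=iv, strand=row[5]))
    return genes


def read_tad_bed(path) -> list[TadDomain]:
    """Read TADs from BED3+name; overlapping TADs on one chromosome are rejected."""
    tads = []
    for lineno, row in _open_rows(path):
        if not row or row[0].startswith(("#", "track", "browser")):
            continue
        try:
            iv = GenomicInterval(row[0], int(row[1]), int(row[2]))
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from None
        name = row[3] if len(row) > 3 and row[3] else f"tad_{lineno}"
        tads.append(TadDomain(tad_id=name, interval=iv))
    by_chrom: dict[str, list[TadDomain]] = {}
    for t in tads:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    offenders = []
    for chrom_tads in by_chrom.values():
        chrom_tads.sort(key=lambda t: t.interval.start)
        for a, b in zip(chrom_tads, chrom_tads[1:]):
            if b.interval.start < a.interval.end:
                offenders.append(f"{a.tad_id}/{b.tad_id}")
    if offenders:
        raise ValueError(f"{path}: overlapping TADs: {', '.join(offenders)}")
    return tads


# --- packaged fixtures -------------------------------------------------------

@dataclass
class Table1Row:
    """One published worked example: a significant peak, its nearest
    differentially expressed gene, and the DR types found in the peak."""

    mark: MarkKind
    interval: GenomicInterval
    peak_log2fc: float
    rare_types: tuple[str, ...]
    gene_id: str
    rna_log2fc: float


@dataclass
class Table2Row:
    """One published highly conserved element."""

    nearest_gene: str
    tad_genes: tuple[str, ...]
    sequence: str  # spaced: HALF SPACER HALF
    motif_type: str
    conserved: dict[str, bool]
    interval: GenomicInterval
    element_class: str


def _fixture_path(name: str):
    return resources.files("raretarget.data").joinpath(name)


def load_table1_fixture() -> list[Table1Row]:
    rows = []
    with _fixture_path("table1.tsv").open() as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            rares = tuple(t for t in rec["rare_types"].split(",") if t != "-")
            rows.append(Table1Row(
                mark=MarkKind(rec["mark"]),
                interval=parse_region(rec["region"]),
                peak_log2fc=float(rec["peak_log2fc"]),
                rare_types=rares,
                gene_id=rec["gene"],
                rna_log2fc=float(rec["rna_log2fc"]),
            ))
    if len(rows) != 27:
        raise ValueError(f"table1 fixture corrupted: {len(rows)} rows, expected 27")
    return rows


_CLADE_COLS = ("rodent", "human", "bird", "reptile", "frog", "fish")


def load_table2_fixture() -> list[Table2Row]:
    rows = []
    with _fixture_path("table2.tsv").open() as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            iv = parse_region(rec["region"])
            seq_len = len(rec["sequence"].replace(" ", ""))
            if seq_len != iv.length:
                raise ValueError(
                    f"table2 fixture corrupted: sequence length {seq_len} != "
                    f"span {iv.length} for {rec['region']}"
                )
            tad_genes = tuple(
                g for g in rec["tad_genes"].split(",")
                if g and g.lower() != "none"
            )
            rows.append(Table2Row(
                nearest_gene=rec["nearest_gene"],
                tad_genes=tad_genes,
                sequence=rec["sequence"],
                motif_type=rec["motif_type"],
                conserved={c: rec[c] == "x" for c in _CLADE_COLS},
                interval=iv,
                element_class=rec["element_class"],
            ))
    if len(rows) != 24:
        raise ValueError(f"table2 fixture corrupted: {len(rows)} rows, expected 24")
    return rows


# --- candidate-target table --------------------------------------------------

CANDIDATE_COLUMNS = [
    "gene_id", "direction", "mark", "peak_region", "peak_log2fc", "link_type",
    "concordant", "rare_type", "rare_region", "rare_strand", "rare_mismatches",
    "element_class", "conserved_to",
]


def write_candidate_table(targets, path) -> None:
    """Write candidate targets as a flat TSV, one row per gene x peak x RARE.

    Peaks without any RARE still get one row with empty RARE columns. Rows
    are sorted by (chrom, start, gene_id) for byte-identical re-runs.
    """
    rows = []
    for t in targets:
        for link in t.links:
            peak = link.peak
            link_rares = [r for r in t.rares if r.peak_region == peak.interval.region_string()]
            if not link_rares:
                rows.append((peak.interval.chrom, peak.interval.start, t.gene_id, [
                    t.gene_id, t.direction.value, peak.mark.value,
                    peak.interval.region_string(), f"{peak.log2fc:g}",
                    link.link_type, str(link.concordant).lower(),
                    "", "", "", "", "", "",
                ]))
            for r in link_rares:
                rows.append((peak.interval.chrom, peak.interval.start, t.gene_id, [
                    t.gene_id, t.direction.value, peak.mark.value,
                    peak.interval.region_string(), f"{peak.log2fc:g}",
                    link.link_type, str(link.concordant).lower(),
                    r.match.motif_type, r.match.interval.region_string(),
                    r.match.strand, str(r.match.mismatches),
                    r.element_class, r.conserved_to or "",
                ]))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANDIDATE_COLUMNS)
        for _, _, _, cells in rows:
            writer.writerow(cells)


def read_candidate_table(path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
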