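"""Reading and writing the per-read phased-variant table and auxiliary files.

The phased table is a 7-column TSV with one line per read observation of a
phased heterozygous site::

    #chrom  pos  base  haplotype  cell_barcode  umi  read_id

``pos`` is 1-based (VCF/samtools convention), ``haplotype`` is H1 or H2 (the
two phased alleles of the sample; labels are sample-local and carry no
parental-origin or cross-sample meaning), ``cell_barcode``/``umi`` are the
10x-style droplet and molecule tags. Lines starting with ``#`` are comments;
the first line must be a header comment. Gene annotations use BED4 with the
standard 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PhasedReadRecord",
    "GeneAnnotation",
    "ParseError",
    "IngestReport",
    "HEADER",
    "read_phased_table",
    "write_phased_table",
    "read_gene_bed",
    "read_gene_list",
    "ingest_alignments",
]

HEADER = "#chrom\tpos\tbase\thaplotype\tcell_barcode\tumi\tread_id"

_BASES = frozenset("ACGT")
_HAPLOTYPES = ("H1", "H2")


class ParseError(ValueError):
    """Malformed line in an input file; the message names the line number."""


@dataclass(frozen=True, slots=True)
class PhasedReadRecord:
    """One sequencing-read observation of one phased allele in one cell."""

    chrom: str
    pos: int
    base: str
    haplotype: str
    cell_barcode: str
    umi: str
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.base not in _BASES:
            raise ValueError(f"base must be one of A/C/G/T, got {self.base!r}")
        if self.haplotype not in _HAPLOTYPES:
            raise ValueError(f"haplotype must be H1 or H2, got {self.haplotype!r}")
        if not self.cell_barcode:
            raise ValueError("cell_barcode must be non-empty")
        if not self.umi:
            raise ValueError("umi must be non-empty")


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """A gene interval, 0-based half-open [start, end) as in BED."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )


@dataclass
class IngestReport:
    """Tally of alignment records skipped while converting to phased records."""

    considered: int = 0
    unmapped: int = 0
    missing_tags: int = 0
    base_mismatch: int = 0
    emitted: int = 0


def read_phased_table(path: str | Path) -> list[PhasedReadRecord]:
    """Parse a phased-table TSV into records, preserving file order.

    The first line must be a ``#`` header; later ``#`` lines are comments.
    Raises :class:`ParseError` (naming the line number) on any malformed
    data line; an empty file after the header yields an empty list.
    """
    path = Path(path)
    records: list[PhasedReadRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ParseError(f"{path}: line 1: missing '#' header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 7):
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 or 7 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, pos_s, base, hap, cb, umi = fields[:6]
            read_id = fields[6] if len(fields) == 7 else ""
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: position {pos_s!r} is not an integer"
                ) from None
            try:
                records.append(
                    PhasedReadRecord(chrom, pos, base, hap, cb, umi, read_id)
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_phased_table(
    records: Iterable[PhasedReadRecord], path: str | Path
) -> None:
    """Write records as the phased-table TSV dialect (header + one line each)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(HEADER + "\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.base}\t{r.haplotype}\t"
                f"{r.cell_barcode}\t{r.umi}\t{r.read_id}\n"
            )


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Parse a BED4 file (chrom, start, end, name) into gene annotations.

    Overlapping intervals are permitted and all retained.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 4 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            try:
                genes.append(GeneAnnotation(name, chrom, start, end))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return genes


def read_gene_list(path: str | Path) -> set[str]:
    """Read a known-escape gene list: one symbol per line, '#' comments."""
    out: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym)
    return out


def ingest_alignments(
    alignment_file: str | Path,
    het_sites: Mapping[int, Mapping[str, str]] | Sequence[tuple[int, Mapping[str, str]]],
) -> tuple[list[PhasedReadRecord], IngestReport]:
    """Convert SAM/BAM alignments over phased heterozygous sites to records.

    Parameters
    ----------
    alignment_file
        SAM or BAM path; reads must carry 10x-style ``CB`` (cell barcode) and
        ``UB`` (UMI) string tags.
    het_sites
        Mapping (or sequence of pairs) from 1-based position to the
        ``{base: haplotype}`` map of that site's two phased alleles, e.g.
        ``{153000: {"A": "H1", "G": "H2"}}``.

    Returns one record per aligned read base matching either phased allele at
    a het site, plus a report counting skipped reads (unmapped, missing tags)
    and non-matching bases.
    """
    import pysam

    sites: dict[int, Mapping[str, str]] = dict(het_sites)
    report = IngestReport()
    records: list[PhasedReadRecord] = []
    path = str(alignment_file)
    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        for aln in af:
            report.considered += 1
            if aln.is_unmapped:
                report.unmapped += 1
                continue
            if not (aln.has_tag("CB") and aln.has_tag("UB")):
                report.missing_tags += 1
                continue
            cb = str(aln.get_tag("CB"))
            umi = str(aln.get_tag("UB"))
            seq = aln.query_sequence
            if seq is None:
                report.missing_tags += 1
                continue
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                pos1 = rpos + 1
                allele_map = sites.get(pos1)
                if allele_map is None:
                    continue
                base = seq[qpos].upper()
                hap = allele_map.get(base)
                if hap is None:
                    report.base_mismatch += 1
                    continue
                records.append(
                    PhasedReadRecord(
                        chrom=af.get_reference_name(aln.reference_id) or "chrX",
                        pos=pos1,
                        base=base,
                        haplotype=hap,
                        cell_barcode=cb,
                        umi=umi,
                        read_id=aln.query_name or "",
                    )
                )
                report.emitted += 1
    return records, report
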