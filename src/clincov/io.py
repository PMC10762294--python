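"""Readers and writers for the three input formats and the report outputs.

Coordinate conventions
----------------------
Coverage and exon BED files are 0-based half-open, the dialect written by
depth tools (mosdepth/bedtools/samtools) and by exome-target references.
ClinVar tabular exports carry 1-based positions; they are converted to
0-based offsets on read (``pos0 = position - 1``).

Chromosome labels are compared after stripping an optional ``chr`` prefix,
so ``chr17`` and ``17`` refer to the same chromosome; records keep the label
they were read with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd

from .errors import FormatError, ParseError

logger = logging.getLogger("clincov")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class CoverageInterval(NamedTuple):
    """One run of constant read depth: half-open [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    depth: int


class ExonRecord(NamedTuple):
    """One merged exon of a gene; ``exon_index`` is 1-based within the gene."""

    chrom: str
    start: int
    end: int
    gene: str
    exon_index: int


class VariantClass(str, Enum):
    GERMLINE = "germline"
    SOMATIC = "somatic"


class SNVRecord(NamedTuple):
    """A pathogenic single-nucleotide locus; ``pos0`` is a 0-based offset."""

    chrom: str
    pos0: int
    gene: str | None
    variant_class: VariantClass


@dataclass
class SNVCoverageSet:
    """Multiset of depths observed at the loci of one variant class."""

    variant_class: VariantClass
    depths: list[int] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.depths)

    def __iter__(self):
        return iter(self.depths)

    def __len__(self) -> int:
        return len(self.depths)


@dataclass
class ClinVarTable:
    """Parsed SNV table: retained records plus the count of skipped rows.

    Rows whose position field is empty, non-numeric or a range (two numbers,
    i.e. not a single-nucleotide locus) are skipped and counted.
    """

    variant_class: VariantClass
    records: list[SNVRecord]
    n_skipped: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ClinVarColumns:
    """Column map for ClinVar-style tables; defaults match the web export."""

    chrom: str = "GRCh38Chromosome"
    position: str = "GRCh38Location"
    gene: str = "Gene(s)"


# ---------------------------------------------------------------------------
# Chromosome label handling
# ---------------------------------------------------------------------------

def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix so dialects compare equal."""
    label = label.strip()
    if len(label) > 3 and label[:3].lower() == "chr":
        return label[3:]
    return label


def chrom_sort_key(label: str):
    """Natural ordering: numeric chromosomes first, then X, Y, MT, others."""
    c = normalize_chrom(label)
    if c.isdigit():
        return (0, int(c), "")
    order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c.upper() in order:
        return (0, order[c.upper()], "")
    return (1, 0, c)


# ---------------------------------------------------------------------------
# Coverage BED
# ---------------------------------------------------------------------------

def read_coverage_bed(
    path: str | Path, chrom: str | None = None
) -> Iterator[CoverageInterval]:
    """Stream a per-base coverage BED (chrom, start, end, depth).

    Yields intervals in file order; when ``chrom`` is given, only that
    chromosome's rows are yielded (label compared after ``chr``-stripping).
    The file is never materialised in full.
    """
    want = normalize_chrom(chrom) if chrom is not None else None
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                start, end, depth = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field: {exc}") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            if depth < 0:
                raise ParseError(f"{path}:{lineno}: negative depth {depth}")
            if want is not None and normalize_chrom(parts[0]) != want:
                continue
            yield CoverageInterval(parts[0], start, end, depth)


def write_coverage_bed(intervals: Iterable[CoverageInterval], path: str | Path) -> Path:
    """Write intervals as a 4-column BED; inverse of :func:`read_coverage_bed`."""
    path = Path(path)
    with path.open("w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.depth}\n")
    return path


def _check_sorted_block(chrom: str, block: list[CoverageInterval]) -> list[CoverageInterval]:
    """Sort an out-of-order chromosome block with a warning; reject overlaps."""
    sorted_ok = all(block[i].start <= block[i + 1].start for i in range(len(block) - 1))
    if not sorted_ok:
        logger.warning("coverage records for chromosome %s are unsorted; sorting", chrom)
        block = sorted(block, key=lambda iv: iv.start)
    for a, b in zip(block, block[1:]):
        if b.start < a.end:
            raise FormatError(
                f"overlapping coverage records on {chrom}: "
                f"[{a.start},{a.end}) and [{b.start},{b.end})"
            )
    return block


def iter_chromosome_coverage(
    path: str | Path,
) -> Iterator[tuple[str, list[CoverageInterval]]]:
    """Yield (normalized chromosome, sorted interval list) per chromosome.

    Memory is bounded by one chromosome. Requires chromosomes to be grouped
    (contiguous blocks), which depth tools guarantee; a chromosome appearing
    in two separate blocks is a format error. Unsorted blocks are sorted with
    a warning.
    """
    current: str | None = None
    block: list[CoverageInterval] = []
    seen: set[str] = set()
    for iv in read_coverage_bed(path):
        c = normalize_chrom(iv.chrom)
        if c != current:
            if current is not None:
                yield current, _check_sorted_block(current, block)
            if c in seen:
                raise FormatError(
                    f"coverage BED is not grouped by chromosome: {iv.chrom} "
                    "appears in more than one block"
                )
            seen.add(c)
            current, block = c, []
        block.append(iv)
    if current is not None:
        yield current, _check_sorted_block(current, block)


# ---------------------------------------------------------------------------
# Exon reference BED
# ---------------------------------------------------------------------------

def read_exon_reference(path: str | Path) -> dict[str, list[ExonRecord]]:
    """Read an exon BED (chrom, start, end, gene) into per-gene merged exons.

    Overlapping or book-ended raw rows (transcript isoforms) of one gene are
    merged into disjoint intervals, sorted by start, then numbered 1..k.
    """
    path = Path(path)
    raw: dict[str, list[tuple[str, int, int]]] = {}
    n_rows = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4 or not parts[3].strip():
                raise ParseError(f"{path}:{lineno}: missing gene-symbol column")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field: {exc}") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            raw.setdefault(parts[3].strip(), []).append((parts[0], start, end))
            n_rows += 1
    if n_rows == 0:
        raise FormatError(f"{path}: exon reference contains no rows")

    reference: dict[str, list[ExonRecord]] = {}
    for gene, rows in raw.items():
        chroms = {normalize_chrom(c) for c, _, _ in rows}
        if len(chroms) > 1:
            raise FormatError(
                f"gene {gene} maps to multiple chromosomes: {sorted(chroms)}"
            )
        chrom = rows[0][0]
        merged = merge_intervals([(s, e) for _, s, e in rows])
        reference[gene] = [
            ExonRecord(chrom, s, e, gene, i) for i, (s, e) in enumerate(merged, start=1)
        ]
    return reference


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; overlapping or book-ended runs merge."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# ClinVar-style SNV tables
# ---------------------------------------------------------------------------

def read_clinvar_table(
    path: str | Path,
    variant_class: VariantClass,
    columns: ClinVarColumns | None = None,
) -> ClinVarTable:
    """Read a ClinVar-style tab-separated table of pathogenic SNV loci.

    1-based positions become 0-based offsets. Rows whose position is empty,
    non-numeric, or a range ("43045000 - 43045100") are skipped and counted;
    ranges are not single-nucleotide loci.
    """
    columns = columns or ClinVarColumns()
    variant_class = VariantClass(variant_class)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [
        name
        for name in (columns.chrom, columns.position, columns.gene)
        if name not in df.columns
    ]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"present: {list(df.columns)}"
        )
    records: list[SNVRecord] = []
    n_skipped = 0
    for chrom, pos, gene in zip(
        df[columns.chrom], df[columns.position], df[columns.gene]
    ):
        pos = pos.strip()
        if not pos.isdigit() or int(pos) < 1:
            n_skipped += 1
            continue
        gene = gene.strip() or None
        records.append(SNVRecord(chrom.strip(), int(pos) - 1, gene, variant_class))
    if n_skipped:
        logger.info(
            "%s: skipped %d row(s) without a single-nucleotide position",
            path,
            n_skipped,
        )
    return ClinVarTable(variant_class, records, n_skipped)
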