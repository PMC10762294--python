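"""Per-gene exon coverage evaluation and reporting.

For each requested gene the coverage of its chromosome is joined onto the
merged exons, every base of the gene span (first exon start to last exon
end, introns included) gets a depth, exons whose minimum per-base depth
falls below the threshold are flagged, and every pathogenic SNV locus inside
the span — intronic or exonic — is scored.

SNVs are attached to a gene by genomic span membership, not by the gene
symbol column of the variant table: symbol strings in ClinVar exports are
multi-valued and inconsistent, coordinates are not. The symbol is carried
through for display only.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ClincovError, UnknownGeneError
from .intervals import CoveredSegment, overlap_join, point_depths
from .io import (
    ClinVarColumns,
    CoverageInterval,
    ExonRecord,
    SNVRecord,
    VariantClass,
    normalize_chrom,
    read_clinvar_table,
    read_coverage_bed,
    read_exon_reference,
)
from .snvscore import _sample_stem

logger = logging.getLogger("clincov")


@dataclass
class GeneProfile:
    """Per-base depth over the gene span plus per-exon covered segments."""

    gene: str
    chrom: str
    span_start: int
    span_end: int
    depths: np.ndarray  # shape (span_end - span_start,), uncovered bases = 0
    exon_segments: list[list[CoveredSegment]]  # one list per merged exon

    def depth_at(self, pos0: int) -> int:
        if not self.span_start <= pos0 < self.span_end:
            raise ClincovError(f"position {pos0} outside span of {self.gene}")
        return int(self.depths[pos0 - self.span_start])


@dataclass(frozen=True)
class ExonRow:
    exon_index: int
    start: int
    end: int
    min_depth: int
    mean_depth: float
    flagged: bool


@dataclass(frozen=True)
class SNVRow:
    variant_class: VariantClass
    pos0: int
    depth: int
    covered: bool  # depth >= threshold
    gene_symbol: str | None = None


@dataclass
class GeneCoverageReport:
    """Tabular per-gene summary: exon rows, SNV rows, per-class fractions.

    ``fractions[vclass]`` is None (reported "NA") when the gene span holds no
    SNV of that class — absence of data, not zero coverage.
    """

    gene: str
    chrom: str
    gene_span: tuple[int, int]
    threshold: int
    exon_rows: list[ExonRow]
    snv_rows: list[SNVRow]
    fractions: dict[VariantClass, float | None]
    profile: GeneProfile

    def to_text(self) -> str:
        lines = [
            "# clincov geneCoverage report",
            f"# gene\t{self.gene}",
            f"# chrom\t{self.chrom}",
            f"# span\t{self.gene_span[0]}-{self.gene_span[1]}",
            f"# threshold\t{self.threshold}",
        ]
        for vc in (VariantClass.GERMLINE, VariantClass.SOMATIC):
            frac = self.fractions[vc]
            text = "NA" if frac is None else f"{frac:.4f}"
            lines.append(f"# {vc.value}_fraction_ge_{self.threshold}x\t{text}")
        lines.append("exon_index\tstart\tend\tmin_depth\tmean_depth\tflagged")
        for row in self.exon_rows:
            lines.append(
                f"{row.exon_index}\t{row.start}\t{row.end}\t{row.min_depth}"
                f"\t{row.mean_depth:.2f}\t{'yes' if row.flagged else 'no'}"
            )
        lines.append("class\tposition\tdepth\tcovered\tgene_symbol")
        for snv in self.snv_rows:
            lines.append(
                f"{snv.variant_class.value}\t{snv.pos0 + 1}\t{snv.depth}"
                f"\t{'yes' if snv.covered else 'no'}\t{snv.gene_symbol or '.'}"
            )
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_text())
        return path


def gene_profile(
    coverage: list[CoverageInterval], exons: list[ExonRecord]
) -> GeneProfile:
    """Build the per-base span depth vector and per-exon covered segments.

    ``coverage`` is one chromosome's sorted records; ``exons`` are the merged
    exons of one gene. Bases with no coverage record — intronic gaps or
    unsequenced exon bases — get depth 0.
    """
    if not exons:
        raise ClincovError("gene has no exons in the reference")
    gene = exons[0].gene
    chrom = exons[0].chrom
    span_start, span_end = exons[0].start, exons[-1].end
    depths = np.zeros(span_end - span_start, dtype=np.int64)
    for seg in overlap_join(coverage, (span_start, span_end)):
        depths[seg.start - span_start : seg.end - span_start] = seg.depth
    exon_segments = [overlap_join(coverage, (ex.start, ex.end)) for ex in exons]
    return GeneProfile(gene, chrom, span_start, span_end, depths, exon_segments)


def flag_exons(
    exon_segments: list[list[CoveredSegment]],
    exons: list[ExonRecord],
    threshold: int,
) -> list[tuple[int, bool]]:
    """Flag each exon whose minimum per-base depth is below the threshold.

    Uncovered bases count as depth 0, so any gap in an exon flags it for any
    positive threshold: a single under-covered base can hide a variant.
    """
    if threshold < 1:
        raise ClincovError(f"threshold must be a positive integer, got {threshold}")
    flags = []
    for ex, segs in zip(exons, exon_segments):
        covered_len = sum(s.end - s.start for s in segs)
        min_depth = min((s.depth for s in segs), default=0)
        if covered_len < ex.end - ex.start:
            min_depth = 0
        flags.append((ex.exon_index, min_depth < threshold))
    return flags


def _exon_stats(
    ex: ExonRecord, segs: list[CoveredSegment], threshold: int
) -> ExonRow:
    length = ex.end - ex.start
    covered_len = sum(s.end - s.start for s in segs)
    min_depth = min((s.depth for s in segs), default=0)
    if covered_len < length:
        min_depth = 0
    mean_depth = sum(s.depth * (s.end - s.start) for s in segs) / length
    return ExonRow(ex.exon_index, ex.start, ex.end, min_depth, mean_depth,
                   min_depth < threshold)


def build_gene_report(
    coverage: list[CoverageInterval],
    exons: list[ExonRecord],
    snvs: list[SNVRecord],
    threshold: int,
) -> GeneCoverageReport:
    """Assemble one gene's report from in-memory inputs.

    ``snvs`` may span the genome; only records on the gene's chromosome and
    inside its span are kept (intronic loci included).
    """
    profile = gene_profile(coverage, exons)
    exon_rows = [
        _exon_stats(ex, segs, threshold)
        for ex, segs in zip(exons, profile.exon_segments)
    ]
    chrom_norm = normalize_chrom(profile.chrom)
    in_span = sorted(
        (
            r
            for r in snvs
            if normalize_chrom(r.chrom) == chrom_norm
            and profile.span_start <= r.pos0 < profile.span_end
        ),
        key=lambda r: (r.pos0, r.variant_class.value),
    )
    depths = point_depths(coverage, [r.pos0 for r in in_span])
    snv_rows = [
        SNVRow(r.variant_class, r.pos0, d, d >= threshold, r.gene)
        for r, d in zip(in_span, depths)
    ]
    fractions: dict[VariantClass, float | None] = {}
    for vc in VariantClass:
        class_rows = [row for row in snv_rows if row.variant_class == vc]
        fractions[vc] = (
            sum(row.covered for row in class_rows) / len(class_rows)
            if class_rows
            else None
        )
    return GeneCoverageReport(
        profile.gene,
        profile.chrom,
        (profile.span_start, profile.span_end),
        threshold,
        exon_rows,
        snv_rows,
        fractions,
        profile,
    )


def run_gene_coverage(
    sample_bed: str | Path,
    exon_reference: str | Path,
    germline_table: str | Path,
    somatic_table: str | Path,
    threshold: int,
    genes: list[str],
    out_dir: str | Path | None = None,
    make_figures: bool = True,
    columns: ClinVarColumns | None = None,
) -> list[GeneCoverageReport]:
    """Evaluate one or more genes of interest against a coverage BED.

    Each gene gets its own report (``<sample>_<gene>.tsv``) and two-panel
    figure (``<sample>_<gene>.png``) when ``out_dir`` is given; multi-gene
    runs are identical to per-gene runs.
    """
    if not genes:
        raise ClincovError("at least one gene symbol is required")
    sample_bed = Path(sample_bed)
    reference = read_exon_reference(exon_reference)
    unknown = [g for g in genes if g not in reference]
    if unknown:
        hints = {
            g: difflib.get_close_matches(g, reference.keys(), n=3) for g in unknown
        }
        detail = "; ".join(
            f"{g} (did you mean: {', '.join(h)})" if h else g
            for g, h in hints.items()
        )
        raise UnknownGeneError(f"gene(s) not in exon reference: {detail}")

    snvs = (
        read_clinvar_table(germline_table, VariantClass.GERMLINE, columns).records
        + read_clinvar_table(somatic_table, VariantClass.SOMATIC, columns).records
    )
    stem = _sample_stem(sample_bed)
    coverage_cache: dict[str, list[CoverageInterval]] = {}
    reports = []
    for gene in genes:
        exons = reference[gene]
        chrom = normalize_chrom(exons[0].chrom)
        if chrom not in coverage_cache:
            block = list(read_coverage_bed(sample_bed, chrom=chrom))
            block.sort(key=lambda iv: iv.start)
            coverage_cache[chrom] = block
        logger.info("evaluating gene %s on chromosome %s", gene, chrom)
        report = build_gene_report(coverage_cache[chrom], exons, snvs, threshold)
        reports.append(report)
        if out_dir is not None:
            out_dir = Path(out_dir)
            report.write(out_dir / f"{stem}_{gene}.tsv")
            if make_figures:
                from .plotting import render_gene_figure

                render_gene_figure(report, out_dir / f"{stem}_{gene}.png")
    return reports
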