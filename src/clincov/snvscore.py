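"""Whole-sample pathogenic-SNV coverage scoring and the CDC statistic.

Clinical Depth Coverage (CDC) summarises how deeply the clinically relevant
loci — pathogenic germline and somatic SNV positions — are sequenced. For a
depth multiset {C(v_1), ..., C(v_N)} it is the smallest positive integer m
minimising

    | sum_i sgn(C(v_i) - m) |,    sgn(0) = 0,

i.e. the balance point where the counts of loci covered above and below m
match: a median-like depth over pathogenic positions, which can differ
substantially from the genome-wide median when coverage is uneven exactly
where it matters. Germline (t=g) and somatic (t=s) classes are scored
separately. The smallest-m tie-break makes the statistic deterministic and
conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ClincovError
from .intervals import point_depths, weighted_median
from .io import (
    ClinVarColumns,
    CoverageInterval,
    SNVCoverageSet,
    SNVRecord,
    VariantClass,
    chrom_sort_key,
    iter_chromosome_coverage,
    normalize_chrom,
    read_clinvar_table,
)

logger = logging.getLogger("clincov")

#: Threshold applied when the optional argument is omitted: depth >= 1,
#: i.e. "covered at all".
DEFAULT_THRESHOLD = 1


# ---------------------------------------------------------------------------
# CDC and per-class statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CDCResult:
    """CDC for one variant class, with its dispersion companion.

    ``spread`` is the sample standard deviation of the depth multiset; it is
    reported alongside CDC as "cdc ± round(spread)".
    """

    variant_class: VariantClass
    cdc: int
    spread: float
    n_variants: int

    def __str__(self) -> str:
        return f"{self.cdc} ± {round(self.spread)}"


def _as_depth_array(depths) -> np.ndarray:
    arr = np.asarray(
        depths.depths if isinstance(depths, SNVCoverageSet) else list(depths),
        dtype=np.int64,
    )
    if arr.size == 0:
        raise ClincovError("no variant depths: empty coverage set")
    if (arr < 0).any():
        raise ClincovError("negative depth in coverage set")
    return arr


def compute_cdc(depths: SNVCoverageSet) -> CDCResult:
    """CDC of a depth multiset: smallest m in [1, max+1] minimising |Σ sgn|.

    The sign-sum at m is (#depths > m) − (#depths < m), evaluated for every
    candidate m via two binary searches on the sorted depths.
    """
    vclass = (
        depths.variant_class
        if isinstance(depths, SNVCoverageSet)
        else VariantClass.GERMLINE
    )
    arr = np.sort(_as_depth_array(depths))
    grid = np.arange(1, int(arr[-1]) + 2)
    below = np.searchsorted(arr, grid, side="left")
    above = arr.size - np.searchsorted(arr, grid, side="right")
    cdc = int(grid[np.argmin(np.abs(above - below))])  # argmin takes first tie
    spread = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return CDCResult(vclass, cdc, spread, int(arr.size))


def fraction_above(depths: SNVCoverageSet, threshold: int) -> float:
    """Fraction of loci with depth >= threshold (inclusive)."""
    if threshold < 1:
        raise ClincovError(f"threshold must be a positive integer, got {threshold}")
    arr = _as_depth_array(depths)
    return float(np.mean(arr >= threshold))


def _lower_median(values: np.ndarray) -> int:
    return int(np.sort(values)[(values.size - 1) // 2])


# ---------------------------------------------------------------------------
# Report types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeRow:
    """Per-chromosome, per-class coverage statistics of pathogenic loci."""

    chrom: str
    variant_class: VariantClass
    n: int
    mean_depth: float
    median_depth: int
    min_depth: int
    max_depth: int
    fraction_ge_threshold: float


@dataclass
class SNVScoreReport:
    """Whole-sample report: per-class CDC, fractions, and chromosome table."""

    sample: str
    threshold: int
    results: dict[VariantClass, CDCResult]
    fractions: dict[VariantClass, float]
    sample_median: int
    chromosome_rows: list[ChromosomeRow]

    def to_text(self) -> str:
        lines = [
            "# clincov snvScore report",
            f"# sample\t{self.sample}",
            f"# threshold\t{self.threshold}",
            f"# sample_coverage_median\t{self.sample_median}",
        ]
        for vc in (VariantClass.GERMLINE, VariantClass.SOMATIC):
            res = self.results[vc]
            lines += [
                f"# {vc.value}_cdc\t{res}",
                f"# {vc.value}_n_variants\t{res.n_variants}",
                f"# {vc.value}_fraction_ge_{self.threshold}x\t"
                f"{self.fractions[vc]:.4f}",
            ]
        lines.append(
            "chrom\tclass\tn\tmean_depth\tmedian_depth\tmin_depth\tmax_depth"
            "\tfraction_ge_threshold"
        )
        for row in self.chromosome_rows:
            lines.append(
                f"{row.chrom}\t{row.variant_class.value}\t{row.n}"
                f"\t{row.mean_depth:.2f}\t{row.median_depth}"
                f"\t{row.min_depth}\t{row.max_depth}"
                f"\t{row.fraction_ge_threshold:.4f}"
            )
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_text())
        return path


# ---------------------------------------------------------------------------
# Scoring pipeline
# ---------------------------------------------------------------------------

def _group_snvs_by_chrom(
    records: list[SNVRecord],
) -> dict[str, list[SNVRecord]]:
    grouped: dict[str, list[SNVRecord]] = {}
    for rec in records:
        grouped.setdefault(normalize_chrom(rec.chrom), []).append(rec)
    for recs in grouped.values():
        recs.sort(key=lambda r: r.pos0)
    return grouped


def score_coverage_blocks(
    blocks,
    germline: list[SNVRecord],
    somatic: list[SNVRecord],
    threshold: int,
    sample: str = "sample",
) -> SNVScoreReport:
    """Score per-chromosome coverage blocks against both SNV classes.

    ``blocks`` yields ``(normalized chrom, sorted CoverageInterval list)``
    pairs, one chromosome at a time, so memory stays bounded by one
    chromosome regardless of genome size. Chromosomes present in the SNV
    tables but absent from the coverage stream score depth 0 for all their
    loci, with a warning: unsequenced pathogenic loci must count as failures,
    not disappear.
    """
    if threshold < 1:
        raise ClincovError(f"threshold must be a positive integer, got {threshold}")
    if not germline and not somatic:
        raise ClincovError("no SNV records parsed from either table")

    snvs = _group_snvs_by_chrom(germline + somatic)
    depth_hist: dict[int, int] = {}
    class_depths = {vc: SNVCoverageSet(vc) for vc in VariantClass}
    per_chrom: dict[str, dict[VariantClass, list[int]]] = {}
    pending = set(snvs)

    for chrom, block in blocks:
        logger.info("processing chromosome %s (%d coverage records)", chrom, len(block))
        for iv in block:
            depth_hist[iv.depth] = depth_hist.get(iv.depth, 0) + (iv.end - iv.start)
        if chrom not in snvs:
            continue
        pending.discard(chrom)
        recs = snvs[chrom]
        dvals = point_depths(block, [r.pos0 for r in recs])
        rows = per_chrom.setdefault(chrom, {vc: [] for vc in VariantClass})
        for rec, d in zip(recs, dvals):
            class_depths[rec.variant_class].depths.append(d)
            rows[rec.variant_class].append(d)

    for chrom in sorted(pending, key=chrom_sort_key):
        logger.warning(
            "chromosome %s has SNV records but no coverage; scoring %d loci at depth 0",
            chrom,
            len(snvs[chrom]),
        )
        rows = per_chrom.setdefault(chrom, {vc: [] for vc in VariantClass})
        for rec in snvs[chrom]:
            class_depths[rec.variant_class].depths.append(0)
            rows[rec.variant_class].append(0)

    if not depth_hist:
        raise ClincovError("coverage BED contains no records")

    results = {}
    fractions = {}
    for vc, cov_set in class_depths.items():
        if cov_set.n_variants:
            results[vc] = compute_cdc(cov_set)
            fractions[vc] = fraction_above(cov_set, threshold)
        else:
            results[vc] = CDCResult(vc, 1, 0.0, 0)
            fractions[vc] = float("nan")

    chrom_rows = []
    for chrom in sorted(per_chrom, key=chrom_sort_key):
        for vc in (VariantClass.GERMLINE, VariantClass.SOMATIC):
            d = np.asarray(per_chrom[chrom][vc], dtype=np.int64)
            if d.size == 0:
                continue
            chrom_rows.append(
                ChromosomeRow(
                    chrom,
                    vc,
                    int(d.size),
                    float(d.mean()),
                    _lower_median(d),
                    int(d.min()),
                    int(d.max()),
                    float(np.mean(d >= threshold)),
                )
            )

    sample_median = weighted_median((w, d) for d, w in depth_hist.items())
    return SNVScoreReport(
        sample, threshold, results, fractions, sample_median, chrom_rows
    )


def run_snv_score(
    sample_bed: str | Path,
    germline_table: str | Path,
    somatic_table: str | Path,
    threshold: int | None = None,
    out_dir: str | Path | None = None,
    columns: ClinVarColumns | None = None,
) -> SNVScoreReport:
    """Score every pathogenic SNV locus of a sample, streaming by chromosome.

    Computes per-class CDC, per-class fraction of loci covered at
    ``threshold`` or deeper (default 1, i.e. covered at all), the
    whole-sample weighted coverage median, and a per-chromosome statistics
    table. When ``out_dir`` is given the report is written as
    ``<sample stem>.snvScore.tsv``.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLD
    sample_bed = Path(sample_bed)
    germline = read_clinvar_table(germline_table, VariantClass.GERMLINE, columns)
    somatic = read_clinvar_table(somatic_table, VariantClass.SOMATIC, columns)
    report = score_coverage_blocks(
        iter_chromosome_coverage(sample_bed),
        germline.records,
        somatic.records,
        threshold,
        sample=_sample_stem(sample_bed),
    )
    if out_dir is not None:
        out = Path(out_dir) / f"{report.sample}.snvScore.tsv"
        report.write(out)
        logger.info("wrote %s", out)
    return report


def _sample_stem(path: Path) -> str:
    name = path.name
    return name[:-4] if name.endswith(".bed") else path.stem
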