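"""Synthetic fixtures with analytically known ground truth.

Generates the three input files every analysis consumes — a per-base
coverage BED, an exon reference BED, and two ClinVar-style SNV tables — from
a declarative :class:`FixtureSpec`, together with a ground-truth record
(CDC, fractions above threshold, sample median, flagged exons) computed
independently of the analysis pipeline by rasterising depths base-by-base
and scanning the CDC objective by brute force.

Depth models:

``ConstantDepth(c)``
    every base of every chromosome at depth c;
``PiecewiseDepth(runs)``
    explicit (start, end, depth) runs per chromosome, everything else
    absent from the BED (uncovered);
``PoissonDepth(lam, seed)``
    i.i.d. Poisson(lam) depth per base — the idealised shape of shotgun
    coverage, without the GC, mappability and insert-size structure of real
    data.

Per-base BED rows merge consecutive equal-depth bases into runs, matching
what depth tools emit, so the interval engine's run handling is exercised
rather than degenerate 1-bp rows.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ClincovError
from .io import merge_intervals, normalize_chrom

logger = logging.getLogger("clincov")


# ---------------------------------------------------------------------------
# Spec types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantDepth:
    depth: int


@dataclass(frozen=True)
class PiecewiseDepth:
    #: chromosome -> list of (start, end, depth) runs; must not overlap
    runs: dict[str, list[tuple[int, int, int]]]


@dataclass(frozen=True)
class PoissonDepth:
    lam: float
    seed: int


@dataclass(frozen=True)
class GeneLayout:
    gene: str
    chrom: str
    exons: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class RandomLoci:
    """Place SNV loci uniformly at random: in exons and/or in introns."""

    n_in_exon: int
    n_in_intron: int = 0
    seed: int = 0


@dataclass
class FixtureSpec:
    chrom_lengths: dict[str, int]
    depth_model: ConstantDepth | PiecewiseDepth | PoissonDepth
    genes: list[GeneLayout] = field(default_factory=list)
    #: per class: explicit [(chrom, pos0), ...] or a RandomLoci placement
    germline: list[tuple[str, int]] | RandomLoci = field(default_factory=list)
    somatic: list[tuple[str, int]] | RandomLoci = field(default_factory=list)
    threshold: int = 15


@dataclass
class Fixture:
    coverage_bed: Path
    exon_bed: Path
    germline_table: Path
    somatic_table: Path
    ground_truth_path: Path
    truth: dict


# ---------------------------------------------------------------------------
# Independent ground-truth primitives (deliberately naive)
# ---------------------------------------------------------------------------

def brute_force_cdc(depths) -> int:
    """Scan every m in [1, max+1] for the smallest |Σ sgn(d − m)| minimiser."""
    depths = list(depths)
    if not depths:
        raise ClincovError("empty depth multiset")
    best_m, best = None, None
    for m in range(1, max(depths) + 2):
        s = abs(sum((d > m) - (d < m) for d in depths))
        if best is None or s < best:
            best_m, best = m, s
    return best_m


def _lower_median(values) -> int:
    values = sorted(values)
    return int(values[(len(values) - 1) // 2])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _rasterize(spec: FixtureSpec) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (depth array, emitted mask) over all declared bases."""
    out = {}
    model = spec.depth_model
    for chrom, length in spec.chrom_lengths.items():
        depth = np.zeros(length, dtype=np.int64)
        emitted = np.zeros(length, dtype=bool)
        if isinstance(model, ConstantDepth):
            depth[:] = model.depth
            emitted[:] = True
        elif isinstance(model, PoissonDepth):
            chrom_salt = zlib.crc32(normalize_chrom(chrom).encode())
            rng = np.random.default_rng([model.seed, chrom_salt])
            depth[:] = rng.poisson(model.lam, size=length)
            emitted[:] = True
        elif isinstance(model, PiecewiseDepth):
            for s, e, d in model.runs.get(chrom, []):
                if not 0 <= s < e <= length:
                    raise ClincovError(
                        f"run ({s},{e}) outside chromosome {chrom} bounds"
                    )
                if emitted[s:e].any():
                    raise ClincovError(f"overlapping runs on {chrom}")
                depth[s:e] = d
                emitted[s:e] = True
        else:  # pragma: no cover - guarded by type hints
            raise ClincovError(f"unknown depth model {model!r}")
        out[chrom] = (depth, emitted)
    return out


def _depth_runs(depth: np.ndarray, emitted: np.ndarray):
    """Maximal runs of constant depth within the emitted mask."""
    n = depth.size
    boundary = np.ones(n, dtype=bool)
    boundary[1:] = (depth[1:] != depth[:-1]) | (emitted[1:] != emitted[:-1])
    starts = np.flatnonzero(boundary)
    ends = np.append(starts[1:], n)
    for s, e in zip(starts, ends):
        if emitted[s]:
            yield int(s), int(e), int(depth[s])


def _place_random_loci(
    placement: RandomLoci, spec: FixtureSpec, salt: int
) -> list[tuple[str, int]]:
    if not spec.genes:
        raise ClincovError("random SNV placement requires gene layouts")
    rng = np.random.default_rng([placement.seed, salt])
    exonic: list[tuple[str, int]] = []
    intronic: list[tuple[str, int]] = []
    for g in spec.genes:
        merged = merge_intervals(g.exons)
        span = (merged[0][0], merged[-1][1])
        exon_bases = {b for s, e in merged for b in range(s, e)}
        for b in range(*span):
            (exonic if b in exon_bases else intronic).append((g.chrom, b))
    loci = []
    for pool, n in ((exonic, placement.n_in_exon), (intronic, placement.n_in_intron)):
        if n > len(pool):
            raise ClincovError(f"cannot place {n} loci in a pool of {len(pool)}")
        idx = rng.choice(len(pool), size=n, replace=False)
        loci.extend(pool[i] for i in idx)
    return sorted(set(loci))


def _resolve_loci(spec: FixtureSpec, which: str) -> list[tuple[str, int]]:
    placement = getattr(spec, which)
    if isinstance(placement, RandomLoci):
        salt = 11 if which == "germline" else 13
        return _place_random_loci(placement, spec, salt)
    loci = sorted(placement)
    for chrom, pos0 in loci:
        if chrom not in spec.chrom_lengths or not 0 <= pos0 < spec.chrom_lengths[chrom]:
            raise ClincovError(f"SNV locus ({chrom}, {pos0}) outside bounds")
    return loci


def _gene_symbol_at(spec: FixtureSpec, chrom: str, pos0: int) -> str:
    for g in spec.genes:
        if normalize_chrom(g.chrom) != normalize_chrom(chrom):
            continue
        merged = merge_intervals(g.exons)
        if merged[0][0] <= pos0 < merged[-1][1]:
            return g.gene
    return ""


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> Fixture:
    """Write the four input files plus a JSON ground-truth record.

    ClinVar-style tables are written with bare chromosome labels ("1") while
    BED files keep the labels of ``chrom_lengths`` as declared, exercising
    the chr-prefix normalisation of the readers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raster = _rasterize(spec)

    coverage_bed = out_dir / "sample.bed"
    with coverage_bed.open("w") as fh:
        for chrom in spec.chrom_lengths:
            depth, emitted = raster[chrom]
            for s, e, d in _depth_runs(depth, emitted):
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")

    exon_bed = out_dir / "exons.bed"
    with exon_bed.open("w") as fh:
        for g in spec.genes:
            if merge_intervals(g.exons) != sorted(g.exons):
                logger.warning(
                    "declared exons of %s overlap; reader will merge them", g.gene
                )
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t{s}\t{e}\t{g.gene}\n")

    loci = {w: _resolve_loci(spec, w) for w in ("germline", "somatic")}
    tables = {}
    for which, path in (
        ("germline", out_dir / "snv_germline.txt"),
        ("somatic", out_dir / "snv_somatic.txt"),
    ):
        with path.open("w") as fh:
            fh.write("Gene(s)\tGRCh38Chromosome\tGRCh38Location\n")
            for chrom, pos0 in loci[which]:
                symbol = _gene_symbol_at(spec, chrom, pos0)
                fh.write(f"{symbol}\t{normalize_chrom(chrom)}\t{pos0 + 1}\n")
        tables[which] = path

    truth = _ground_truth(spec, raster, loci)
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return Fixture(
        coverage_bed, exon_bed, tables["germline"], tables["somatic"],
        truth_path, truth,
    )


def _ground_truth(spec, raster, loci) -> dict:
    t = spec.threshold
    truth: dict = {"threshold": t, "classes": {}, "genes": {}}

    emitted_depths = []
    for chrom in spec.chrom_lengths:
        depth, emitted = raster[chrom]
        emitted_depths.append(depth[emitted])
    all_emitted = np.concatenate(emitted_depths) if emitted_depths else np.array([])
    if all_emitted.size:
        truth["sample_median"] = _lower_median(all_emitted.tolist())

    class_depths = {}
    for which, positions in loci.items():
        depths = [int(raster[c][0][p]) for c, p in positions]
        class_depths[which] = depths
        if depths:
            truth["classes"][which] = {
                "n": len(depths),
                "cdc": brute_force_cdc(depths),
                "fraction_ge_threshold": sum(d >= t for d in depths) / len(depths),
            }

    for g in spec.genes:
        merged = merge_intervals(g.exons)
        span = (merged[0][0], merged[-1][1])
        depth, _ = raster[g.chrom]
        flagged = [
            i
            for i, (s, e) in enumerate(merged, start=1)
            if int(depth[s:e].min()) < t
        ]
        gene_truth = {"n_exons": len(merged), "flagged_exons": flagged,
                      "span": list(span), "snv_fractions": {}}
        for which, positions in loci.items():
            in_span = [
                int(depth[p])
                for c, p in positions
                if normalize_chrom(c) == normalize_chrom(g.chrom)
                and span[0] <= p < span[1]
            ]
            gene_truth["snv_fractions"][which] = (
                sum(d >= t for d in in_span) / len(in_span) if in_span else None
            )
        truth["genes"][g.gene] = gene_truth
    return truth
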