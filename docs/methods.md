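# Methods

## Model and procedure

`clincov` evaluates the coverage of a sequencing sample at two resolutions.

**Whole-sample (snv-score).** Every pathogenic SNV locus from two
ClinVar-style tables — germline and somatic, analysed separately — is
point-queried against the sample's per-base coverage. Each class yields a
depth multiset {C(v₁), …, C(v_N)}, from which three summaries are computed:

1. *Clinical Depth Coverage (CDC)*: the smallest positive integer m
   minimising |Σᵢ sgn(C(vᵢ) − m)| with sgn(0) = 0, scanned over
   m ∈ {1, …, max depth + 1}. The sign-sum counts loci above m minus loci
   below m, so its zero crossing is a median-like balance point over
   clinically relevant positions. The raw argmin of the (signed) sum is not
   finite — the sum is non-increasing in m — so the absolute value is the
   quantity minimised; the smallest-m tie-break makes the statistic
   deterministic and errs low, the conservative direction for QC. For odd N
   with a unique middle value CDC coincides with the ordinary median (a
   property test asserts this). CDC is reported with a companion spread,
   the sample standard deviation (ddof = 1; 0 for a single locus) of the
   depth multiset, rounded for display as "CDC ± s".
2. *Breadth above threshold*: the fraction of loci with depth ≥ t
   (inclusive comparison).
3. *Sample coverage median*: the lower weighted median of the entire
   coverage BED — each record contributes its depth with weight
   (end − start) — computed from a depth histogram accumulated during the
   stream, never by expansion.

**Per-gene (gene-coverage).** Exon rows of a reference BED are merged per
gene (overlapping or book-ended transcript isoforms union into disjoint
exons, numbered 1..k by position). The gene span runs from the first merged
exon's start to the last one's end, introns included. The chromosome's
coverage is joined onto the span and onto each exon; an exon is flagged when
its minimum per-base depth — with uncovered bases counting as 0 — falls
below the threshold (strict <). Minimum rather than mean drives the flag
because one under-covered base can hide a variant; the mean is reported
alongside for judgment. Every pathogenic SNV whose coordinate falls inside
the span is reported with its depth, intronic loci included: inclusion is
decided by position, not by the gene-symbol string of the variant table,
because ClinVar symbol fields are multi-valued and inconsistent while
coordinates are not. A class with no loci in the span reports "NA", not 0.

## Coordinates and input conventions

Coverage and exon BEDs are 0-based half-open; ClinVar-style tables are
1-based and converted on read (pos0 = position − 1). Chromosome labels are
compared after stripping an optional `chr` prefix, since depth tools and
ClinVar exports disagree on the dialect. Table rows whose position field is
empty, non-numeric, or a range ("a - b" spans are not single-nucleotide
loci) are skipped and counted; the count is part of the parse result. The
table column map is configurable and defaults to the ClinVar web-export
names (`GRCh38Chromosome`, `GRCh38Location`, `Gene(s)`).

## Streaming and the interval engine

Per-base BEDs for a whole genome are large, so the pipeline consumes them
one chromosome at a time: memory is bounded by a single chromosome's
records, and the depth histogram for the sample median is folded in during
the same pass. The geometric core is a forward sweep over sorted,
non-overlapping records — an overlap join that clips records to a target
and merges adjacent equal-depth runs, and a point-depth query that walks
records and sorted positions together in linear time. Sorted input is the
contract (depth tools emit it); an unsorted chromosome block is sorted in
memory with a warning rather than rejected, while overlapping records and
chromosomes split across non-adjacent blocks are hard errors. A chromosome
present in an SNV table but absent from the BED scores all its loci at
depth 0 with a warning — unsequenced pathogenic loci are failures, not
missing data.

## Parameters

| parameter | meaning | default |
|---|---|---|
| threshold t | minimum depth (×) for a locus/exon to count as reliably assayed | 1 for snv-score (covered at all); required for gene-coverage |
| ClinVar column map | names of the chromosome/position/gene columns | ClinVar web export |
| figure colors | germline dots red, somatic dark blue, flagged exons red, exon fill light blue | overridable per call |
| upper-panel pooling | spans beyond 200 kb are max-pooled to ≤200k points | max-pooling preserves every sub-threshold dip |

## Figures

The two-panel figure shows per-base depth over the gene span (top,
genomic x-axis) and exon-only coverage (bottom). Each exon's horizontal
width is proportional to its length with a minimum visible width of 1% of
the summed exon length, so genes with dozens of short exons remain legible;
boundaries are marked and tick labels carry exon index and genomic start.
All semantic content — dot coordinates, flagged-exon extents, panel
geometry — lives in a `GeneFigureSpec` built before rendering, and tests
assert on that spec rather than on pixels, which keeps them independent of
the matplotlib backend.

## Synthetic data

The `simulate` module generates all three input formats from a declarative
spec with three depth models: constant (exact, closed-form truth),
piecewise-constant runs (exact truth for hand-built scenarios such as the
bimodal {5, 5, 50, 50} case), and i.i.d. Poisson(λ) per base — the
idealised shape of shotgun coverage. Ground truth (CDC by brute-force grid
scan, breadths, weighted median, flagged exons) is computed by a separate,
deliberately naive rasterisation path so pipeline tests compare two
independent routes. Emitted BEDs merge equal-depth neighbouring bases into
runs, matching real depth-tool output.

What the Poisson model does **not** emulate: GC- and mappability-driven
coverage waves, insert-size correlation between neighbouring bases,
alignment artefacts, and the off-target/on-target contrast of capture
exomes. Passing tests therefore demonstrate correctness of the statistics
and plumbing under known truth, not robustness to every artefact of real
libraries; on real data the same code paths run, but the numbers carry the
biases of the upstream aligner and depth tool.

Default study conditions for the end-to-end recomputation
(`scripts/acceptance.py`): mean depth λ = 20×, two chromosomes totalling
250 kb, three genes (22 merged exons), 1000 loci per class of which 85% are
exonic, threshold 15×. At these settings the CDC recovers λ within ±1 and
the 15× breadth tracks the analytic tail P(Poisson(20) ≥ 15) ≈ 0.895; the
sizes keep a full run in seconds while leaving ~10⁵-scale record counts to
exercise the streaming path. Note that with per-base-independent Poisson
depths every multi-kilobase exon almost surely contains a base below 15×,
so min-based flagging marks all exons — the expected behaviour of the
statistic, not an artefact.

## Numerical choices and edge cases

- All depths, CDC and medians are integers; the lower median (no
  interpolation) is used throughout, matching integer read counts.
- CDC's candidate grid starts at m = 1, so an all-zero depth multiset
  yields CDC 1 (with breadth 0 at any threshold) rather than a degenerate 0.
- Duplicate loci in a table each count once per row: ClinVar lists distinct
  alleles at one position, and N is the number of referenced variants.
- Empty depth multisets, empty references and zero parsed SNVs are errors,
  not silent empty reports.
- Reports are plain tab-separated text with a `#` header block; identical
  inputs produce byte-identical reports.

## Limitations

- Single-sample, single-technology view: no multi-sample joint QC.
- BED in, not BAM: generating per-base depth is upstream
  (mosdepth/bedtools/samtools).
- No transcript-level (isoform) reporting; exons are the per-gene union.
- The ClinVar tables are taken as given; no significance filtering or
  download logic is included, so results inherit whatever query produced
  the tables.
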