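# clincov

Clinical depth-of-coverage QC for sequencing samples.

Variant calling is only as trustworthy as the coverage under it. Before a
diagnostic lab interprets a genome or exome — short-read or long-read — it
needs to know whether the positions that *matter clinically* were actually
sequenced deeply enough: the loci of known pathogenic SNVs, and the exons of
the genes under investigation. Genome-wide mean or median depth can look
fine while precisely those positions sit in coverage holes.

`clincov` takes a per-base coverage BED (the output dialect of
mosdepth/bedtools/samtools run on a BAM), ClinVar-style tables of pathogenic
germline and somatic SNV loci, and an exon reference, and answers two
questions:

- **snv-score** — across the whole sample, how well are all pathogenic SNV
  loci covered? Reports the Clinical Depth Coverage statistic, the fraction
  of loci covered at or above a chosen threshold, the sample-wide coverage
  median, and a per-chromosome statistics table.
- **gene-coverage** — for chosen genes, which exons are reliably covered?
  Produces a per-gene report (per-exon min/mean depth, flagged exons,
  per-SNV depths) and a two-panel figure: depth over the whole gene span on
  top, exon-by-exon coverage below, with sub-threshold exons drawn in red
  and pathogenic germline (red) / somatic (dark blue) SNV loci as dots.

## The CDC statistic

For a variant class *t* ∈ {germline, somatic} with loci v₁,…,v_N and
per-locus depths C(vᵢ), the Clinical Depth Coverage is the smallest
positive integer *m* minimising

```
CDC(t) = argmin_{m ∈ ℕ⁺} | Σᵢ sgn( C(vᵢ) − m ) | ,   sgn(0) = 0
```

— the depth at which the number of pathogenic loci covered above *m*
balances the number covered below: a median-like depth computed over
clinically relevant positions only. It is reported as `CDC ± s`, where `s`
is the rounded sample standard deviation of the locus depths. A sample can
have a comfortable genome-wide median yet a lower CDC, meaning coverage is
systematically thinner exactly where pathogenic variants live.

Loci absent from the coverage BED count as depth 0: an unsequenced
pathogenic position is the most important failure to surface, not a row to
drop.

## Worked example

Build a tiny synthetic sample with known truth and score it (the
`clincov.simulate` module generates all three input formats):

```python
from clincov import *

spec = FixtureSpec(
    chrom_lengths={"chr1": 2000},
    depth_model=PiecewiseDepth({"chr1": [(100, 110, 5), (200, 210, 50),
                                         (300, 400, 7)]}),
    genes=[GeneLayout("G1", "chr1", ((100, 120), (200, 220)))],
    germline=[("chr1", 105), ("chr1", 106), ("chr1", 205), ("chr1", 206)],
    somatic=[("chr1", 305), ("chr1", 306), ("chr1", 307)],
)
fx = make_fixture(spec, "demo")
report = run_snv_score(fx.coverage_bed, fx.germline_table,
                       fx.somatic_table, threshold=15)
print(report.to_text())
```

prints

```
# clincov snvScore report
# sample	sample
# threshold	15
# sample_coverage_median	7
# germline_cdc	6 ± 26
# germline_n_variants	4
# germline_fraction_ge_15x	0.5000
# somatic_cdc	7 ± 0
# somatic_n_variants	3
# somatic_fraction_ge_15x	0.0000
chrom	class	n	mean_depth	median_depth	min_depth	max_depth	fraction_ge_threshold
1	germline	4	27.50	5	5	50	0.5000
1	somatic	3	7.00	7	7	7	0.0000
```

The germline depths are {5, 5, 50, 50}: two loci below and two above any
depth between 6 and 49, so the sign-sum is zero on that whole range and the
smallest-m tie-break gives CDC = 6 — a deliberately conservative summary of
a bimodal coverage profile whose *mean* (27.5×) would look reassuring. Half
the germline loci reach the 15× threshold; none of the somatic loci (all at
7×) do.

The same inputs drive the per-gene view from the shell:

```
clincov gene-coverage demo/sample.bed demo/exons.bed \
        demo/snv_germline.txt demo/snv_somatic.txt 15 G1
clincov snv-score demo/sample.bed demo/snv_germline.txt demo/snv_somatic.txt 15
```

writing `sample_G1.tsv` and the two-panel figure `sample_G1.png` into the
working directory (`--out-dir` to redirect). `geneCoverage` / `snvScore`
are accepted as aliases, and the snv-score threshold may be omitted
(default 1× = covered at all).

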