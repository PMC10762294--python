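"""Per-gene profiles, exon flagging and the geneCoverage pipeline."""

import numpy as np
import pytest

from clincov import (
    CoverageInterval,
    ExonRecord,
    UnknownGeneError,
    VariantClass,
    flag_exons,
    gene_profile,
    run_gene_coverage,
)
from clincov.errors import ClincovError


def _cov(*triples):
    return [CoverageInterval("chr1", s, e, d) for s, e, d in triples]


def _exons(*pairs, gene="G1"):
    return [
        ExonRecord("chr1", s, e, gene, i) for i, (s, e) in enumerate(pairs, start=1)
    ]


class TestGeneProfile:
    def test_single_exon_constant_depth(self):
        prof = gene_profile(_cov((100, 110, 5)), _exons((100, 110)))
        assert prof.depths.tolist() == [5] * 10
        assert [tuple(s) for s in prof.exon_segments[0]] == [(100, 110, 5)]

    def test_intronic_gap_is_zero(self):
        prof = gene_profile(
            _cov((100, 110, 8), (200, 210, 9)), _exons((100, 110), (200, 210))
        )
        assert prof.depths[10:100].tolist() == [0] * 90
        assert prof.depth_at(205) == 9

    def test_no_exons_is_error(self):
        with pytest.raises(ClincovError, match="no exons"):
            gene_profile(_cov((0, 10, 1)), [])

    def test_span_vector_matches_rasterization_oracle(self):
        rng = np.random.default_rng(11)
        pos, cov = 0, []
        while pos < 900:
            pos += int(rng.integers(0, 20))
            length = int(rng.integers(1, 40))
            cov.append((pos, pos + length, int(rng.integers(0, 50))))
            pos += length
        exons = _exons((50, 200), (400, 450), (700, 880))
        prof = gene_profile(_cov(*cov), exons)
        oracle = np.zeros(880 - 50, dtype=int)
        for s, e, d in cov:
            lo, hi = max(s, 50), min(e, 880)
            if lo < hi:
                oracle[lo - 50 : hi - 50] = d
        assert prof.depths.tolist() == oracle.tolist()


class TestFlagExons:
    def _flags(self, cov, exons, threshold):
        prof = gene_profile(cov, exons)
        return flag_exons(prof.exon_segments, exons, threshold)

    def test_fully_covered_above_threshold_not_flagged(self):
        assert self._flags(_cov((0, 10, 20)), _exons((0, 10)), 15) == [(1, False)]

    def test_coverage_gap_forces_flag(self):
        # bases 0..8 at depth 20, base 9 uncovered -> depth 0 -> flagged
        assert self._flags(_cov((0, 9, 20)), _exons((0, 10)), 15) == [(1, True)]

    def test_strict_comparison_at_minimum(self):
        assert self._flags(_cov((0, 10, 14)), _exons((0, 10)), 15) == [(1, True)]
        assert self._flags(_cov((0, 10, 15)), _exons((0, 10)), 15) == [(1, False)]


class TestRunGeneCoverage:
    def test_constant_fixture_all_covered(self, constant_fixture, tmp_path):
        _, fx = constant_fixture
        (report,) = run_gene_coverage(
            fx.coverage_bed, fx.exon_bed, fx.germline_table, fx.somatic_table,
            15, ["GENEA"], out_dir=tmp_path,
        )
        assert not any(r.flagged for r in report.exon_rows)
        assert report.fractions[VariantClass.GERMLINE] == 1.0
        assert report.fractions[VariantClass.SOMATIC] == 1.0
        assert all(s.covered for s in report.snv_rows)
        assert (tmp_path / "sample_GENEA.tsv").exists()
        assert (tmp_path / "sample_GENEA.png").stat().st_size > 0

    def test_threshold_above_constant_depth_flags_everything(self, constant_fixture):
        _, fx = constant_fixture
        (report,) = run_gene_coverage(
            fx.coverage_bed, fx.exon_bed, fx.germline_table, fx.somatic_table,
            25, ["GENEA"],
        )
        assert all(r.flagged for r in report.exon_rows)
        assert report.fractions[VariantClass.GERMLINE] == 0.0

    def test_mixed_depths_give_hand_counted_fraction(self, piecewise_fixture):
        _, fx = piecewise_fixture
        (report,) = run_gene_coverage(
            fx.coverage_bed, fx.exon_bed, fx.germline_table, fx.somatic_table,
            15, ["G1"],
        )
        # germline depths in G1 span: {5, 5, 50, 50} -> half reach 15x
        assert report.fractions[VariantClass.GERMLINE] == 0.5
        # no somatic locus falls inside the span -> not applicable, not 0
        assert report.fractions[VariantClass.SOMATIC] is None
        assert "NA" in report.to_text()

    def test_intronic_snv_in_span_is_included(self, tmp_path):
        (tmp_path / "s.bed").write_text("chr1\t0\t1000\t30\n")
        (tmp_path / "e.bed").write_text("chr1\t100\t110\tG1\nchr1\t300\t310\tG1\n")
        header = "Gene(s)\tGRCh38Chromosome\tGRCh38Location\n"
        (tmp_path / "g.txt").write_text(header + "G1\t1\t201\n")  # intron, pos0=200
        (tmp_path / "o.txt").write_text(header + "G1\t1\t5\n")  # outside span
        (report,) = run_gene_coverage(
            tmp_path / "s.bed", tmp_path / "e.bed", tmp_path / "g.txt",
            tmp_path / "o.txt", 15, ["G1"],
        )
        assert [(s.pos0, s.depth) for s in report.snv_rows] == [(200, 30)]

    def test_snv_depth_consistent_with_profile(self, piecewise_fixture):
        _, fx = piecewise_fixture
        (report,) = run_gene_coverage(
            fx.coverage_bed, fx.exon_bed, fx.germline_table, fx.somatic_table,
            15, ["G1"],
        )
        for snv in report.snv_rows:
            assert snv.depth == report.profile.depth_at(snv.pos0)

    def test_multi_gene_equals_single_gene_runs(self, tmp_path):
        (tmp_path / "s.bed").write_text("chr1\t0\t1000\t30\nchr2\t0\t500\t8\n")
        (tmp_path / "e.bed").write_text(
            "chr1\t100\t150\tGA\nchr2\t50\t80\tGB\nchr2\t200\t250\tGB\n"
        )
        header = "Gene(s)\tGRCh38Chromosome\tGRCh38Location\n"
        (tmp_path / "g.txt").write_text(header + "GA\t1\t120\nGB\t2\t60\n")
        (tmp_path / "m.txt").write_text(header + "GB\t2\t220\n")
        args = (
            tmp_path / "s.bed", tmp_path / "e.bed", tmp_path / "g.txt",
            tmp_path / "m.txt", 15,
        )
        multi = run_gene_coverage(*args, ["GA", "GB"])
        singles = [run_gene_coverage(*args, [g])[0] for g in ("GA", "GB")]
        assert [r.to_text() for r in multi] == [r.to_text() for r in singles]

    def test_unknown_gene_lists_near_matches(self, constant_fixture):
        _, fx = constant_fixture
        with pytest.raises(UnknownGeneError, match="GENEA"):
            run_gene_coverage(
                fx.coverage_bed, fx.exon_bed, fx.germline_table, fx.somatic_table,
                15, ["GENEB"],
            )
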