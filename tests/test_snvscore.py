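"""CDC statistic and the whole-sample snvScore pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clincov import (
    SNVCoverageSet,
    VariantClass,
    compute_cdc,
    fraction_above,
    run_snv_score,
)
from clincov.errors import ClincovError


def brute_cdc(depths):
    """Exhaustive scan of |Σ sgn(d − m)| over the full m grid."""
    best_m, best = None, None
    for m in range(1, max(depths) + 2):
        s = abs(sum((d > m) - (d < m) for d in depths))
        if best is None or s < best:
            best_m, best = m, s
    return best_m


def _gset(depths):
    return SNVCoverageSet(VariantClass.GERMLINE, list(depths))


class TestComputeCDC:
    @pytest.mark.parametrize(
        "depths,expected",
        [
            ([7] * 5, 7),          # constant set: sign-sum is 0 only at m=7
            ([10, 20, 30], 20),    # balance point = middle value
            ([5, 5, 50, 50], 6),   # tie across 6..49; smallest m wins
            ([0, 0, 0], 1),        # all-uncovered loci still yield a valid m
        ],
    )
    def test_known_multisets(self, depths, expected):
        assert compute_cdc(_gset(depths)).cdc == expected

    def test_result_fields(self):
        res = compute_cdc(_gset([10, 20, 30]))
        assert res.n_variants == 3
        assert res.spread == pytest.approx(10.0)  # sample std, ddof=1
        assert str(res) == "20 ± 10"

    def test_single_variant_has_zero_spread(self):
        res = compute_cdc(_gset([12]))
        assert (res.cdc, res.spread) == (12, 0.0)

    def test_empty_set_is_error(self):
        with pytest.raises(ClincovError, match="empty"):
            compute_cdc(_gset([]))

    @given(
        st.lists(st.integers(0, 300), min_size=1, max_size=200),
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_exhaustive_scan(self, depths):
        assert compute_cdc(_gset(depths)).cdc == brute_cdc(depths)

    @given(st.sets(st.integers(0, 300), min_size=1, max_size=41))
    @settings(max_examples=200, derandomize=True)
    def test_odd_distinct_multiset_gives_statistical_median(self, values):
        values = sorted(values)
        if len(values) % 2 == 0:
            values = values[:-1]
        expected = values[len(values) // 2]
        if expected == 0:  # grid starts at 1; a zero median maps to m=1
            expected = 1
        assert compute_cdc(_gset(values)).cdc == expected


class TestFractionAbove:
    @pytest.mark.parametrize(
        "depths,threshold,expected",
        [
            ([10, 20, 30], 15, 2 / 3),
            ([0, 0], 1, 0.0),
            ([15], 15, 1.0),  # inclusive comparison
        ],
    )
    def test_examples(self, depths, threshold, expected):
        assert fraction_above(_gset(depths), threshold) == pytest.approx(expected)

    @given(st.lists(st.integers(0, 100), min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_non_increasing_in_threshold_and_breadth_at_one(self, depths):
        s = _gset(depths)
        fracs = [fraction_above(s, t) for t in range(1, 30)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] == sum(d > 0 for d in depths) / len(depths)


class TestRunSNVScore:
    def test_constant_fixture(self, constant_fixture, tmp_path):
        _, fx = constant_fixture
        report = run_snv_score(
            fx.coverage_bed, fx.germline_table, fx.somatic_table, 15,
            out_dir=tmp_path,
        )
        for vc in VariantClass:
            assert report.results[vc].cdc == 20
            assert report.fractions[vc] == 1.0
        assert report.sample_median == 20
        assert (tmp_path / "sample.snvScore.tsv").exists()

    def test_bimodal_fixture_matches_brute_force(self, piecewise_fixture):
        _, fx = piecewise_fixture
        report = run_snv_score(fx.coverage_bed, fx.germline_table, fx.somatic_table, 15)
        assert report.results[VariantClass.GERMLINE].cdc == 6
        assert report.results[VariantClass.SOMATIC].cdc == 7

    def test_chromosome_counts_sum_to_totals(self, piecewise_fixture):
        _, fx = piecewise_fixture
        report = run_snv_score(fx.coverage_bed, fx.germline_table, fx.somatic_table, 15)
        for vc in VariantClass:
            total = sum(
                r.n for r in report.chromosome_rows if r.variant_class == vc
            )
            assert total == report.results[vc].n_variants

    def test_default_threshold_means_covered_at_all(self, piecewise_fixture):
        _, fx = piecewise_fixture
        report = run_snv_score(fx.coverage_bed, fx.germline_table, fx.somatic_table)
        assert report.threshold == 1
        assert report.fractions[VariantClass.GERMLINE] == 1.0

    def test_snv_chromosome_missing_from_bed_scores_zero(self, tmp_path, caplog):
        bed = tmp_path / "s.bed"
        bed.write_text("chr1\t0\t100\t30\n")
        header = "Gene(s)\tGRCh38Chromosome\tGRCh38Location\n"
        germ = tmp_path / "g.txt"
        germ.write_text(header + "G\t1\t50\nG\t9\t10\n")
        som = tmp_path / "s.txt"
        som.write_text(header + "G\t1\t60\n")
        with caplog.at_level("WARNING", logger="clincov"):
            report = run_snv_score(bed, germ, som, 15)
        assert any("no coverage" in r.message for r in caplog.records)
        assert report.results[VariantClass.GERMLINE].n_variants == 2
        assert report.fractions[VariantClass.GERMLINE] == 0.5  # depth 30 and 0
        assert report.results[VariantClass.SOMATIC].cdc == 30

    def test_zero_snvs_overall_is_error(self, tmp_path):
        bed = tmp_path / "s.bed"
        bed.write_text("chr1\t0\t100\t30\n")
        empty = tmp_path / "g.txt"
        empty.write_text("Gene(s)\tGRCh38Chromosome\tGRCh38Location\n")
        with pytest.raises(ClincovError, match="no SNV records"):
            run_snv_score(bed, empty, empty, 15)
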