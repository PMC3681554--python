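import numpy as np
import pytest

from sweepscan.simulate import make_table_fixture
from sweepscan.sweep_scan import (
    HighDensityScanParams,
    LowDensityScanParams,
    SweepRegion,
    VARIABLE_SENTINEL,
    region_size,
    scan_high_density,
    scan_low_density,
)

from conftest import build_matrix, random_panel
from oracles import (
    check_hd_region_constraints,
    check_hd_region_maximality,
    hd_regions_reference,
    low_density_regions_by_enumeration,
)


class TestRegionSize:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (1_712_261, 2_013_659, 301_398),
            (1_673_108, 2_024_737, 351_629),
            (42, 42, 0),
        ],
    )
    def test_end_minus_start_convention(self, start, end, expected):
        assert region_size(start, end) == expected

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            region_size(10, 5)


class TestSweepRegionInvariants:
    def test_counts_must_be_consistent(self):
        with pytest.raises(ValueError):
            SweepRegion("P", "1", 100, 200, n_total=5, n_fixed=3, n_variable=1)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            SweepRegion("P", "1", 200, 200, n_total=2, n_fixed=2, n_variable=0)


class TestScanLowDensity:
    def test_published_row_geometry(self):
        # 11 adjacent monomorphic loci spanning 1,712,261..2,013,659
        matrix, panel = make_table_fixture(
            [("1", 1_712_261, 2_013_659, 11, 0)], "Angus", samples=20
        )
        regions = scan_low_density(
            matrix, panel, "Angus", LowDensityScanParams(n_min=6)
        )
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_total, r.size) == (1_712_261, 2_013_659, 11, 301_398)
        assert r.n_variable == 0
        assert VARIABLE_SENTINEL not in r.fixed_haplotype

    def test_all_polymorphic_panel_yields_nothing(self):
        calls = np.tile(np.array([0, 1, 2, 1, 0, 1], dtype=np.int8), (30, 1))
        matrix, panel = build_matrix(calls)
        assert scan_low_density(matrix, panel, "P1", LowDensityScanParams()) == []

    def test_span_below_threshold_rejected(self):
        # 6 monomorphic loci spanning only 150 kb
        pos = [10_000 + i * 30_000 for i in range(6)]
        matrix, panel = build_matrix(np.zeros((6, 10)), pos=pos)
        params = LowDensityScanParams(n_min=6, span_min=200_000)
        assert scan_low_density(matrix, panel, "P1", params) == []

    def test_unknown_population_rejected(self, tiny_matrix):
        matrix, panel = tiny_matrix
        with pytest.raises(KeyError):
            scan_low_density(matrix, panel, "nope", LowDensityScanParams())

    def test_variable_loci_counted_and_masked_in_haplotype(self):
        # middle locus has 1 het among 100 samples: MAF 0.005 <= 0.01
        calls = np.zeros((7, 100), dtype=np.int8)
        calls[3, 0] = 1
        pos = [100_000 * (i + 1) for i in range(7)]
        matrix, panel = build_matrix(calls, pos=pos)
        params = LowDensityScanParams(n_min=5, span_min=200_000)
        (region,) = scan_low_density(matrix, panel, "P1", params)
        assert region.n_total == 7
        assert region.n_variable == 1
        assert region.fixed_haplotype[3] == VARIABLE_SENTINEL

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_interval_oracle(self, seed):
        rng = np.random.default_rng(seed)
        matrix, panel = random_panel(rng, n_loci=90, n_samples=8)
        params = LowDensityScanParams(n_min=4, span_min=60_000)
        got = [
            (r.chrom, r.start, r.end, r.n_total)
            for r in scan_low_density(matrix, panel, "Pop", params)
        ]
        expected = low_density_regions_by_enumeration(matrix, panel, "Pop", params)
        assert got == expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(123)
        matrix, panel = random_panel(rng, n_loci=150, n_samples=10, mono_fraction=0.6)
        base = LowDensityScanParams(n_min=3, span_min=0, maf_max=0.05)
        n_base = len(scan_low_density(matrix, panel, "Pop", base))
        for tighter in (
            LowDensityScanParams(n_min=4, span_min=0, maf_max=0.05),
            LowDensityScanParams(n_min=3, span_min=50_000, maf_max=0.05),
            LowDensityScanParams(n_min=3, span_min=0, maf_max=0.0),
        ):
            assert len(scan_low_density(matrix, panel, "Pop", tighter)) <= n_base

    def test_max_gap_splits_runs(self):
        pos = [10_000, 20_000, 30_000, 500_000, 510_000, 520_000]
        matrix, panel = build_matrix(np.zeros((6, 10)), pos=pos)
        params = LowDensityScanParams(n_min=3, span_min=0, max_gap=100_000)
        regions = scan_low_density(matrix, panel, "P1", params)
        assert [(r.start, r.end) for r in regions] == [
            (10_000, 30_000), (500_000, 520_000)
        ]


class TestScanHighDensity:
    def test_published_row_geometry(self):
        # 214 loci over 202,799 bp with 3 isolated variable loci, M = 11
        matrix, panel = make_table_fixture(
            [("9", 1_384_189, 1_586_988, 214, 3)], "Hanwoo", samples=11
        )
        (region,) = scan_high_density(matrix, panel, "Hanwoo", HighDensityScanParams())
        assert (region.start, region.end) == (1_384_189, 1_586_988)
        assert (region.n_total, region.n_fixed, region.n_variable) == (214, 211, 3)
        assert region.size == 202_799

    def test_four_contiguous_variable_loci_never_inside_a_region(self):
        calls = np.zeros((30, 10), dtype=np.int8)
        for i in (13, 14, 15, 16):
            calls[i, :4] = 1  # MAF 0.2 > 1/20: variable run of length 4
        matrix, panel = build_matrix(calls)
        params = HighDensityScanParams(n_min=5, span_min=0)
        regions = scan_high_density(matrix, panel, "P1", params)
        assert regions, "flanking fixed runs should still be reported"
        for r in regions:
            assert not (r.start <= 140_000 and r.end >= 170_000)

    def test_single_heterozygote_does_not_break_a_sweep(self):
        calls = np.zeros((25, 10), dtype=np.int8)
        calls[12, 0] = 1  # MAF exactly 1/(2M): fixed by definition
        matrix, panel = build_matrix(calls)
        params = HighDensityScanParams(n_min=20, span_min=100_000)
        (region,) = scan_high_density(matrix, panel, "P1", params)
        assert region.n_total == 25
        assert region.n_variable == 0

    def test_interior_early_variable_locus_is_tolerated(self):
        # variable locus at index 6 of 60 (like a 248-SNP sweep differing at
        # its 7th SNP): whole-interval fraction 1/60 passes even though the
        # prefix fraction at admission time would not
        calls = np.zeros((60, 10), dtype=np.int8)
        calls[6, :3] = 1
        pos = [2_000 * (i + 1) for i in range(60)]
        matrix, panel = build_matrix(calls, pos=pos)
        params = HighDensityScanParams(n_min=20, span_min=100_000)
        (region,) = scan_high_density(matrix, panel, "P1", params)
        assert region.n_total == 60
        assert region.n_variable == 1
        assert region.fixed_haplotype[6] == VARIABLE_SENTINEL

    @pytest.mark.parametrize("seed", range(40))
    def test_constraints_maximality_and_reference_agreement(self, seed):
        rng = np.random.default_rng(1_000 + seed)
        matrix, panel = random_panel(
            rng, n_loci=100, n_samples=6, missing_rate=0.05, mono_fraction=0.7
        )
        params = HighDensityScanParams(n_min=8, span_min=0, variable_fraction_max=0.15)
        regions = scan_high_density(matrix, panel, "Pop", params)
        for r in regions:
            assert check_hd_region_constraints(matrix, panel, "Pop", r, params) == []
            assert check_hd_region_maximality(matrix, panel, "Pop", r, params) == []
        got = [(r.chrom, r.start, r.end, r.n_total, r.n_variable) for r in regions]
        assert sorted(got) == hd_regions_reference(matrix, panel, "Pop", params)

    def test_regions_disjoint_within_population(self):
        rng = np.random.default_rng(77)
        matrix, panel = random_panel(rng, n_loci=200, mono_fraction=0.8)
        params = HighDensityScanParams(n_min=5, span_min=0, variable_fraction_max=0.2)
        regions = scan_high_density(matrix, panel, "Pop", params)
        by_chrom: dict[str, list] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for rs in by_chrom.values():
            rs.sort(key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                assert a.end < b.start
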