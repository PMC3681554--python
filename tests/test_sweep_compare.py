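import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import datasets
from sweepscan.genotype_model import GenotypeMatrix, PopulationPanel, SnpMap
from sweepscan.sweep_compare import (
    IncomparableError,
    core_haplotype_distance,
    core_interval,
    group_overlapping_regions,
    validate_across_assays,
)
from sweepscan.sweep_scan import (
    HighDensityScanParams,
    SweepRegion,
    scan_high_density,
)

from oracles import group_by_transitive_closure, validated_by_all_pairs


def region(pop, chrom, start, end, n=5):
    return SweepRegion(pop, chrom, start, end, n_total=n, n_fixed=n, n_variable=0)


@st.composite
def region_lists(draw):
    n = draw(st.integers(min_value=1, max_value=12))
    out = []
    for i in range(n):
        chrom = draw(st.sampled_from(["1", "2"]))
        start = draw(st.integers(min_value=1, max_value=500))
        length = draw(st.integers(min_value=1, max_value=200))
        out.append(region(f"P{i % 3}", chrom, start, start + length))
    return out


class TestGrouping:
    def test_published_bta16_block(self):
        members = [
            region("Jersey", "16", 45_376_614, 45_874_144),
            region("Angus", "16", 45_425_579, 45_874_144),
            region("Hereford", "16", 45_464_423, 45_874_144),
        ]
        (group,) = group_overlapping_regions(members)
        assert len(group.members) == 3
        assert core_interval(group) == (45_464_423, 45_874_144, False)

    def test_disjoint_intervals_stay_separate(self):
        groups = group_overlapping_regions(
            [region("A", "1", 100, 200), region("B", "1", 300, 400)]
        )
        assert len(groups) == 2
        assert all(len(g.members) == 1 for g in groups)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(region_lists())
    def test_matches_transitive_closure_oracle(self, regions):
        describe = lambda r: (r.population, r.chrom, r.start, r.end)
        got = sorted(
            sorted(describe(m) for m in g.members)
            for g in group_overlapping_regions(regions)
        )
        expected = sorted(
            sorted(describe(regions[i]) for i in g)
            for g in group_by_transitive_closure(regions)
        )
        assert got == expected

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(region_lists(), st.randoms(use_true_random=False))
    def test_partition_is_permutation_invariant(self, regions, rnd):
        shuffled = regions[:]
        rnd.shuffle(shuffled)
        as_key = lambda gs: sorted(
            tuple(sorted((m.population, m.start, m.end) for m in g.members))
            for g in gs
        )
        assert as_key(group_overlapping_regions(regions)) == as_key(
            group_overlapping_regions(shuffled)
        )

    def test_core_contained_in_every_member(self):
        members = [
            region("A", "3", 100, 900),
            region("B", "3", 400, 1_200),
            region("C", "3", 350, 950),
        ]
        (group,) = group_overlapping_regions(members)
        start, end, empty = core_interval(group)
        assert not empty
        for m in members:
            assert m.start <= start and end <= m.end

    def test_chained_overlap_without_common_core_is_flagged(self):
        chain = [
            region("A", "1", 1, 11), region("B", "1", 9, 21), region("C", "1", 19, 31)
        ]
        (group,) = group_overlapping_regions(chain)
        assert len(group.members) == 3
        _, _, empty = core_interval(group)
        assert empty and group.core_empty

    def test_singleton_core_is_its_own_interval(self):
        (group,) = group_overlapping_regions([region("A", "2", 5, 50)])
        assert core_interval(group) == (5, 50, False)


def _two_population_sweep_matrix(n_core=248, mismatch_at=6):
    """Two populations fixed for haplotypes differing at one core locus."""
    n = n_core + 8  # 4 flanking polymorphic loci each side
    pos = [2_000 * (i + 1) for i in range(n)]
    smap = SnpMap.from_arrays(
        [f"m{i}" for i in range(n)], ["16"] * n, pos, ["A"] * n, ["G"] * n
    )
    n_a, n_b = 12, 12
    calls = np.zeros((n, n_a + n_b), dtype=np.int8)
    half_a, half_b = n_a // 2, n_a + n_b // 2
    for i in list(range(4)) + list(range(n - 4, n)):
        calls[i, :half_a] = 2
        calls[i, n_a:half_b] = 2
    calls[4 + mismatch_at, n_a:] = 2  # population B fixed for the alternate
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    matrix = GenotypeMatrix(smap, samples, calls)
    panel = PopulationPanel(
        {s: ("PopA" if s.startswith("A") else "PopB") for s in samples}
    )
    return matrix, panel


class TestCoreHaplotype:
    def test_identical_sweeps_have_distance_zero(self):
        matrix, panel = _two_population_sweep_matrix(n_core=40, mismatch_at=None or 0)
        # undo the mismatch: make both populations all-reference
        matrix.calls[4, :] = 0
        params = HighDensityScanParams(n_min=20, span_min=0)
        regions = scan_high_density(matrix, panel, "PopA", params) + scan_high_density(
            matrix, panel, "PopB", params
        )
        (group,) = group_overlapping_regions(regions)
        cmp = core_haplotype_distance(matrix, panel, group, "PopA", "PopB")
        assert cmp.hamming_distance == 0
        assert cmp.n_shared_core_loci == 40

    def test_single_mismatch_at_seventh_of_248_core_loci(self):
        matrix, panel = _two_population_sweep_matrix(n_core=248, mismatch_at=6)
        params = HighDensityScanParams(n_min=20, span_min=0)
        regions = scan_high_density(matrix, panel, "PopA", params) + scan_high_density(
            matrix, panel, "PopB", params
        )
        (group,) = group_overlapping_regions(regions)
        cmp = core_haplotype_distance(matrix, panel, group, "PopA", "PopB")
        assert cmp.n_shared_core_loci == 248
        assert cmp.hamming_distance == 1
        assert cmp.n_skipped_variable == 0

    def test_distance_is_symmetric_and_reflexive(self):
        matrix, panel = _two_population_sweep_matrix(n_core=30, mismatch_at=10)
        params = HighDensityScanParams(n_min=20, span_min=0)
        regions = scan_high_density(matrix, panel, "PopA", params) + scan_high_density(
            matrix, panel, "PopB", params
        )
        (group,) = group_overlapping_regions(regions)
        ab = core_haplotype_distance(matrix, panel, group, "PopA", "PopB")
        ba = core_haplotype_distance(matrix, panel, group, "PopB", "PopA")
        aa = core_haplotype_distance(matrix, panel, group, "PopA", "PopA")
        assert ab.hamming_distance == ba.hamming_distance == 1
        assert aa.hamming_distance == 0

    def test_random_fixed_vectors_match_direct_count(self):
        rng = np.random.default_rng(42)
        n = 60
        pos = [1_000 * (i + 1) for i in range(n)]
        smap = SnpMap.from_arrays(
            [f"m{i}" for i in range(n)], ["5"] * n, pos, ["A"] * n, ["G"] * n
        )
        hap_a = rng.integers(0, 2, n)
        hap_b = rng.integers(0, 2, n)
        calls = np.concatenate(
            [np.repeat(2 * hap_a[:, None], 6, axis=1),
             np.repeat(2 * hap_b[:, None], 6, axis=1)], axis=1
        ).astype(np.int8)
        samples = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
        matrix = GenotypeMatrix(smap, samples, calls)
        panel = PopulationPanel(
            {s: ("PopA" if s.startswith("A") else "PopB") for s in samples}
        )
        params = HighDensityScanParams(n_min=20, span_min=0)
        regions = scan_high_density(matrix, panel, "PopA", params) + scan_high_density(
            matrix, panel, "PopB", params
        )
        (group,) = group_overlapping_regions(regions)
        cmp = core_haplotype_distance(matrix, panel, group, "PopA", "PopB")
        assert cmp.hamming_distance == int(np.sum(hap_a != hap_b))

    def test_no_shared_core_loci_is_incomparable(self):
        matrix, panel = _two_population_sweep_matrix(n_core=30, mismatch_at=5)
        regions = [
            region("PopA", "16", 10, 20),
            region("PopB", "16", 15, 30),
        ]
        (group,) = group_overlapping_regions(regions)
        with pytest.raises((IncomparableError, ValueError)):
            core_haplotype_distance(matrix, panel, group, "PopA", "PopB")


class TestCrossAssayValidation:
    def test_published_catalogues_yield_five_regions(self):
        discovery = datasets.catalogue_regions(datasets.load_snp50_sweeps())
        validation = datasets.catalogue_regions(
            datasets.load_hd_breed_specific_sweeps()
        ) + datasets.catalogue_regions(datasets.load_hd_shared_sweeps())
        results = validate_across_assays(discovery, validation)
        confirmed = [r.discovery for r in results if r.validated]
        groups = group_overlapping_regions(confirmed)
        assert len(groups) == 5
        assert sorted(g.chrom for g in groups) == ["1", "13", "16", "16", "18"]

    def test_empty_validation_set(self):
        results = validate_across_assays([region("A", "1", 1, 10)], [])
        assert len(results) == 1 and not results[0].validated

    def test_cross_population_support_counts_unless_restricted(self):
        d = [region("Holstein", "13", 15_456_721, 15_683_571)]
        v = [region("Wagyu", "13", 15_493_906, 15_739_251)]
        assert validate_across_assays(d, v)[0].validated
        assert not validate_across_assays(d, v, same_population_only=True)[0].validated

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(region_lists(), region_lists(), st.booleans())
    def test_matches_all_pairs_oracle(self, discovery, validation, same_pop):
        results = validate_across_assays(discovery, validation, same_pop)
        got = {i for i, r in enumerate(results) if r.validated}
        assert got == validated_by_all_pairs(discovery, validation, same_pop)
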