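"""Cross-population grouping, core intervals, core haplotypes and validation.

Sweeps called independently in several populations rarely share exact
boundaries; overlapping calls are clustered by single linkage (>= 1 bp
overlap on the same chromosome) and each cluster's *core region* is the
intersection of its member intervals.  The *core haplotype* — the vector of
fixed alleles at loci inside the core — is compared between populations by
mismatch count: identical (or near-identical) core haplotypes across
populations make a chance origin of the shared signal vanishingly unlikely.

A discovery-set region is *validated* when at least one region from an
independent (typically higher-density) scan overlaps it, in any population
unless ``same_population_only`` is set — cross-population confirmation is
deliberate, since phylogenetically close populations may carry the same swept
haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .genotype_model import GenotypeMatrix, PopulationPanel, chrom_sort_key
from .sweep_scan import VARIABLE_SENTINEL, SweepRegion


class IncomparableError(ValueError):
    """Raised when two populations share no core loci to compare."""


@dataclass(frozen=True)
class SweepOverlapGroup:
    """Overlapping sweeps from one or more populations on one chromosome.

    ``core_start``/``core_end`` is the intersection (max of starts, min of
    ends); when pairwise-overlap chaining links members with no common
    intersection the group is kept whole and flagged ``core_empty``.
    """

    chrom: str
    members: tuple[SweepRegion, ...]
    core_start: int
    core_end: int
    core_empty: bool
    union_start: int
    union_end: int
    populations: frozenset[str]


def _overlaps(a: SweepRegion, b: SweepRegion) -> bool:
    # closed 1-based intervals: >= 1 shared bp
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def _make_group(members: list[SweepRegion]) -> SweepOverlapGroup:
    core_start = max(r.start for r in members)
    core_end = min(r.end for r in members)
    return SweepOverlapGroup(
        chrom=members[0].chrom,
        members=tuple(sorted(members, key=lambda r: (r.start, r.end, r.population))),
        core_start=core_start,
        core_end=core_end,
        core_empty=core_start >= core_end if len(members) > 1 else False,
        union_start=min(r.start for r in members),
        union_end=max(r.end for r in members),
        populations=frozenset(r.population for r in members),
    )


def group_overlapping_regions(regions: Sequence[SweepRegion]) -> list[SweepOverlapGroup]:
    """Single-linkage clustering of regions by >= 1 bp interval overlap.

    Every region lands in exactly one group; groups are sorted by
    (chromosome, union start). Input order does not affect the partition.
    """
    by_chrom: dict[str, list[SweepRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    groups: list[SweepOverlapGroup] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        members = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.population))
        current: list[SweepRegion] = []
        reach = None
        for r in members:
            if current and r.start <= reach:
                current.append(r)
                reach = max(reach, r.end)
            else:
                if current:
                    groups.append(_make_group(current))
                current = [r]
                reach = r.end
        if current:
            groups.append(_make_group(current))
    return sorted(groups, key=lambda g: (chrom_sort_key(g.chrom), g.union_start))


def core_interval(group: SweepOverlapGroup) -> tuple[int, int, bool]:
    """(max of member starts, min of member ends, empty-core flag)."""
    if not group.members:
        raise ValueError("empty group")
    start = max(r.start for r in group.members)
    end = min(r.end for r in group.members)
    return start, end, (start >= end and len(group.members) > 1)


@dataclass(frozen=True)
class CoreHaplotypeComparison:
    """Mismatch count between two populations' fixed alleles at core loci."""

    n_shared_core_loci: int
    hamming_distance: int
    n_skipped_variable: int


def core_haplotype_distance(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    group: SweepOverlapGroup,
    pop_a: str,
    pop_b: str,
) -> CoreHaplotypeComparison:
    """Positionwise mismatches between fixed-allele vectors at shared core loci.

    Loci are matched by (chrom, pos) so that regions called on assays with
    different marker names remain comparable.  Sentinel (variable) positions
    in either member are skipped and counted separately.  Symmetric in
    ``pop_a``/``pop_b``.
    """
    core_start, core_end, empty = core_interval(group)
    if empty:
        raise IncomparableError("group has an empty core interval")
    id_to_idx = matrix.locus_index_by_id()

    def core_alleles(pop: str) -> dict[int, str]:
        out: dict[int, str] = {}
        found = False
        for r in group.members:
            if r.population != pop:
                continue
            found = True
            if r.locus_ids is None or r.fixed_haplotype is None:
                raise ValueError(
                    f"member region of {pop!r} carries no locus-level haplotype"
                )
            for lid, allele in zip(r.locus_ids, r.fixed_haplotype):
                pos = int(matrix.snp_map.pos[id_to_idx[lid]])
                if core_start <= pos <= core_end:
                    out[pos] = allele
        if not found:
            raise KeyError(f"population {pop!r} contributes no member region")
        return out

    alleles_a = core_alleles(pop_a)
    alleles_b = core_alleles(pop_b)
    shared = sorted(set(alleles_a) & set(alleles_b))
    if not shared:
        raise IncomparableError(
            f"no shared core loci between {pop_a!r} and {pop_b!r}"
        )
    skipped = sum(
        1 for p in shared
        if alleles_a[p] == VARIABLE_SENTINEL or alleles_b[p] == VARIABLE_SENTINEL
    )
    dist = sum(
        1 for p in shared
        if alleles_a[p] != VARIABLE_SENTINEL
        and alleles_b[p] != VARIABLE_SENTINEL
        and alleles_a[p] != alleles_b[p]
    )
    return CoreHaplotypeComparison(len(shared), dist, skipped)


@dataclass(frozen=True)
class ValidationResult:
    """One discovery region and the validation regions overlapping it."""

    discovery: SweepRegion
    supports: tuple[SweepRegion, ...]

    @property
    def validated(self) -> bool:
        return len(self.supports) > 0


def validate_across_assays(
    discovery: Sequence[SweepRegion],
    validation: Sequence[SweepRegion],
    same_population_only: bool = False,
) -> list[ValidationResult]:
    """Overlap every discovery region against an independent region set.

    Both sets must share a coordinate system.  A result is returned for every
    discovery region; ``validated`` is true when >= 1 validation region
    overlaps it by >= 1 bp on the same chromosome (restricted to the same
    population only if requested).
    """
    by_chrom: dict[str, list[SweepRegion]] = {}
    for r in validation:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: list[ValidationResult] = []
    for d in discovery:
        hits = [
            v for v in by_chrom.get(d.chrom, ())
            if _overlaps(d, v)
            and (not same_population_only or v.population == d.population)
        ]
        hits.sort(key=lambda r: (r.start, r.end, r.population))
        out.append(ValidationResult(d, tuple(hits)))
    return out


def groups_to_frame(groups: Sequence[SweepOverlapGroup]) -> pd.DataFrame:
    """Block-style table: one row per member region, grouped by cluster."""
    rows = []
    for gi, g in enumerate(groups, start=1):
        for r in g.members:
            rows.append(
                {
                    "group": gi,
                    "chrom": g.chrom,
                    "population": r.population,
                    "start": r.start,
                    "end": r.end,
                    "n_total": r.n_total,
                    "size": r.size,
                    "core_start": g.core_start,
                    "core_end": g.core_end,
                    "core_empty": g.core_empty,
                    "n_populations": len(g.populations),
                }
            )
    return pd.DataFrame(rows)


def validation_to_frame(results: Sequence[ValidationResult]) -> pd.DataFrame:
    """Validation report (one row per discovery x supporting region pair)."""
    rows = []
    for res in results:
        base = {
            "population": res.discovery.population,
            "chrom": res.discovery.chrom,
            "start": res.discovery.start,
            "end": res.discovery.end,
            "n_fixed": res.discovery.n_fixed,
            "n_variable": res.discovery.n_variable,
            "size": res.discovery.size,
            "validated": res.validated,
        }
        if not res.supports:
            rows.append({**base, "support_population": None,
                         "support_start": None, "support_end": None})
        for s in res.supports:
            rows.append({**base, "support_population": s.population,
                         "support_start": s.start, "support_end": s.end})
    return pd.DataFrame(rows)
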