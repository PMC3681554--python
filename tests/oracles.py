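"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity, not speed, and deliberately avoids
the library's own algorithms: MAF by explicit allele tallying, region
discovery by exhaustive interval enumeration, grouping by fixed-point
transitive closure, validation by all-pairs overlap testing.
"""

from __future__ import annotations

from sweepscan.genotype_model import MISSING, GenotypeMatrix, PopulationPanel
from sweepscan.sweep_scan import HighDensityScanParams, LowDensityScanParams


def maf_by_tally(matrix: GenotypeMatrix, panel: PopulationPanel, population: str,
                 locus: int) -> float | None:
    """MAF by per-sample allele counting; None when no calls exist."""
    members = set(panel.samples_for(population))
    alt = total = 0
    for j, sample in enumerate(matrix.samples):
        if sample not in members:
            continue
        call = int(matrix.calls[locus, j])
        if call == MISSING:
            continue
        alt += call
        total += 2
    if total == 0:
        return None
    f = alt / total
    return min(f, 1.0 - f)


def low_density_regions_by_enumeration(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    params: LowDensityScanParams,
) -> list[tuple[str, int, int, int]]:
    """All maximal admissible intervals, by testing every (i, j) pair.

    Returns (chrom, start, end, n_total) tuples sorted by position.
    """
    smap = matrix.snp_map
    out = []
    for chrom in smap.chromosomes:
        sl = smap.chrom_slice(chrom)
        idx = list(range(sl.start, sl.stop))
        low = []
        for k in idx:
            m = maf_by_tally(matrix, panel, population, k)
            low.append(m is not None and m <= params.maf_max)
        n = len(idx)
        admissible = []
        for i in range(n):
            for j in range(i + params.n_min - 1, n):
                if not all(low[i: j + 1]):
                    continue
                if params.max_gap is not None and any(
                    smap.pos[idx[k + 1]] - smap.pos[idx[k]] > params.max_gap
                    for k in range(i, j)
                ):
                    continue
                if smap.pos[idx[j]] - smap.pos[idx[i]] < params.span_min:
                    continue
                admissible.append((i, j))
        maximal = [
            (i, j) for (i, j) in admissible
            if not any(a <= i and j <= b and (a, b) != (i, j) for a, b in admissible)
        ]
        for i, j in sorted(maximal):
            out.append((chrom, int(smap.pos[idx[i]]), int(smap.pos[idx[j]]), j - i + 1))
    return out


def hd_variable_by_tally(matrix: GenotypeMatrix, panel: PopulationPanel,
                         population: str, locus: int) -> bool | None:
    """Variable iff MAF > 1/(2M); None when unclassifiable (no calls)."""
    members = set(panel.samples_for(population))
    m_called = sum(
        1 for j, s in enumerate(matrix.samples)
        if s in members and int(matrix.calls[locus, j]) != MISSING
    )
    if m_called == 0:
        return None
    maf = maf_by_tally(matrix, panel, population, locus)
    return maf > 1.0 / (2 * m_called)


def check_hd_region_constraints(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    region,
    params: HighDensityScanParams,
) -> list[str]:
    """Violated-constraint names for a reported high-density region."""
    smap = matrix.snp_map
    sl = smap.chrom_slice(region.chrom)
    idx = [k for k in range(sl.start, sl.stop)
           if region.start <= smap.pos[k] <= region.end]
    problems = []
    flags = [hd_variable_by_tally(matrix, panel, population, k) for k in idx]
    if len(idx) != region.n_total:
        problems.append("n_total mismatch with map")
    if len(idx) < params.n_min:
        problems.append("n_min")
    if smap.pos[idx[-1]] - smap.pos[idx[0]] < params.span_min:
        problems.append("span_min")
    if any(f is None for f in flags):
        problems.append("unclassifiable locus inside region")
    n_var = sum(bool(f) for f in flags)
    if n_var != region.n_variable:
        problems.append("n_variable mismatch")
    if n_var > params.variable_fraction_max * len(idx):
        problems.append("variable_fraction")
    run = 0
    for f in flags:
        run = run + 1 if f else 0
        if run > params.max_contiguous_variable:
            problems.append("contiguous_variable")
            break
    if flags and (flags[0] or flags[-1]):
        problems.append("variable boundary locus")
    return problems


def check_hd_region_maximality(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    region,
    params: HighDensityScanParams,
) -> list[str]:
    """A reported region must not extend to the adjacent fixed locus.

    Extending the interval to the nearest fixed locus beyond either boundary
    must break a rule (fraction, contiguity, an unclassifiable locus, or a
    max_gap cut); otherwise the region was not maximal.
    """
    smap = matrix.snp_map
    sl = smap.chrom_slice(region.chrom)
    idx = list(range(sl.start, sl.stop))
    flags = {k: hd_variable_by_tally(matrix, panel, population, k) for k in idx}
    inside = [k for k in idx if region.start <= smap.pos[k] <= region.end]
    first, last = inside[0], inside[-1]

    def admissible(span_idx: list[int]) -> bool:
        fl = [flags[k] for k in span_idx]
        if any(f is None for f in fl):
            return False
        if params.max_gap is not None and any(
            smap.pos[span_idx[i + 1]] - smap.pos[span_idx[i]] > params.max_gap
            for i in range(len(span_idx) - 1)
        ):
            return False
        n_var = sum(bool(f) for f in fl)
        if n_var > params.variable_fraction_max * len(fl):
            return False
        run = 0
        for f in fl:
            run = run + 1 if f else 0
            if run > params.max_contiguous_variable:
                return False
        return True

    problems = []
    nxt = next((k for k in idx if k > last and flags[k] is False), None)
    if nxt is not None and admissible(list(range(first, nxt + 1))):
        problems.append("extendable right")
    prv = next((k for k in reversed(idx) if k < first and flags[k] is False), None)
    if prv is not None and admissible(list(range(prv, last + 1))):
        problems.append("extendable left")
    return problems


def hd_regions_reference(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    params: HighDensityScanParams,
) -> list[tuple[str, int, int, int, int]]:
    """Slow, list-based re-implementation of the greedy delimitation policy.

    Returns (chrom, start, end, n_total, n_variable) tuples.
    """
    smap = matrix.snp_map
    out = []
    for chrom in smap.chromosomes:
        sl = smap.chrom_slice(chrom)
        idx = list(range(sl.start, sl.stop))
        flags = [hd_variable_by_tally(matrix, panel, population, k) for k in idx]
        # split into segments at None, at >k variable runs and at large gaps
        segments: list[list[int]] = []
        current: list[int] = []
        var_run: list[int] = []
        for local, (k, f) in enumerate(zip(idx, flags)):
            gap_break = (
                params.max_gap is not None and current
                and smap.pos[k] - smap.pos[(var_run or current)[-1]] > params.max_gap
            )
            if f is None or gap_break:
                if current:
                    segments.append(current)
                current, var_run = [], []
                if gap_break and f is not None:
                    (var_run if f else current).append(k)
                continue
            if f:
                var_run.append(k)
                if len(var_run) > params.max_contiguous_variable:
                    if current:
                        segments.append(current)
                    current, var_run = [], []
            else:
                current.extend(var_run)
                var_run = []
                current.append(k)
        if current:
            segments.append(current)
        for seg in segments:
            seg_flags = [flags[idx.index(k)] for k in seg]
            while seg and seg_flags[0]:
                seg, seg_flags = seg[1:], seg_flags[1:]
            while seg and seg_flags[-1]:
                seg, seg_flags = seg[:-1], seg_flags[:-1]
            a = 0
            n = len(seg)
            var_starts = [i for i in range(n)
                          if seg_flags[i] and (i == 0 or not seg_flags[i - 1])]
            while a < n:
                if seg_flags[a]:
                    a += 1
                    continue
                cands = sorted(
                    {c for c in [rs - 1 for rs in var_starts if rs - 1 >= a] + [n - 1]
                     if c >= a and not seg_flags[c]},
                    reverse=True,
                )
                chosen = None
                for b in cands:
                    n_var = sum(seg_flags[a: b + 1])
                    if n_var <= params.variable_fraction_max * (b - a + 1):
                        chosen = b
                        break
                if chosen is None:
                    a += 1
                    continue
                n_tot = chosen - a + 1
                span = smap.pos[seg[chosen]] - smap.pos[seg[a]]
                if n_tot >= params.n_min and span >= params.span_min:
                    out.append(
                        (chrom, int(smap.pos[seg[a]]), int(smap.pos[seg[chosen]]),
                         n_tot, int(sum(seg_flags[a: chosen + 1])))
                    )
                    a = chosen + 1
                else:
                    nxt = next((rs for rs in var_starts if rs > a), None)
                    if nxt is None:
                        break
                    a = nxt + 1
    return sorted(out)


def group_by_transitive_closure(regions) -> list[frozenset[int]]:
    """Partition region indices by repeated merging of overlapping pairs."""
    def overlap(a, b):
        return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end

    groups = [{i} for i in range(len(regions))]
    changed = True
    while changed:
        changed = False
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                if any(overlap(regions[i], regions[j])
                       for i in groups[gi] for j in groups[gj]):
                    groups[gi] |= groups[gj]
                    del groups[gj]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(g) for g in groups]


def validated_by_all_pairs(discovery, validation, same_population_only=False):
    """Indices of discovery regions overlapped by >= 1 validation region."""
    hits = set()
    for i, d in enumerate(discovery):
        for v in validation:
            if d.chrom != v.chrom:
                continue
            if same_population_only and d.population != v.population:
                continue
            if d.start <= v.end and v.start <= d.end:
                hits.add(i)
    return hits
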