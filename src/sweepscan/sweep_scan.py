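"""Detection of putative completed selective sweeps as contiguous low-MAF runs.

Two rule sets are implemented, matching the two assay densities they were
designed for:

* **Low density** (50K-like panels, median spacing ~37 kb): a sweep is a
  maximal run of map-adjacent loci, each with MAF <= ``maf_max`` (default
  0.01, allowing for genotyping error and new mutation), of at least
  ``n_min`` loci spanning at least ``span_min`` bp (defaults 5 and 200 kb).

* **High density** (HD-like panels, median spacing ~1 kb): each locus is
  classified *variable* iff its MAF exceeds 1/(2M), where M is the number of
  called individuals at the locus — i.e. more than one heterozygote.  A sweep
  region must contain at least ``n_min`` loci (default 20) spanning at least
  ``span_min`` bp (default 100 kb), with at most ``variable_fraction_max``
  (default 5%) of its loci variable and no more than
  ``max_contiguous_variable`` (default 3) consecutive variable loci; region
  boundaries are always fixed loci.

Region size follows the convention ``end - start`` (positions of the last and
first SNP of the run), *not* ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_model import (
    GenotypeMatrix,
    PopulationPanel,
    alt_frequency_vector,
    chrom_sort_key,
    n_called_vector,
)

VARIABLE_SENTINEL = "N"
"""Placeholder in ``fixed_haplotype`` at loci that are not fixed."""


def region_size(start: int, end: int) -> int:
    """Span of a region in bp: ``end - start`` (the tables' convention)."""
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    return end - start


@dataclass(frozen=True)
class LowDensityScanParams:
    """Run-length / span / MAF thresholds for the low-density scan.

    ``n_min`` is the breed-specific run length N; panels with a larger
    monomorphic fraction (SNP ascertainment bias) need a larger N to hold the
    expected false-positive count down (see :mod:`sweepscan.error_model`).
    """

    n_min: int = 5
    span_min: int = 200_000
    maf_max: float = 0.01
    max_gap: Optional[int] = None  # optional cap on adjacent-marker distance

    def __post_init__(self) -> None:
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        if self.span_min < 0:
            raise ValueError("span_min must be >= 0")
        if not (0.0 <= self.maf_max < 0.5):
            raise ValueError("maf_max must be in [0, 0.5)")
        if self.max_gap is not None and self.max_gap < 1:
            raise ValueError("max_gap must be >= 1 when set")


@dataclass(frozen=True)
class HighDensityScanParams:
    """Thresholds for the high-density scan (variable = MAF > 1/(2M))."""

    n_min: int = 20
    span_min: int = 100_000
    variable_fraction_max: float = 0.05
    max_contiguous_variable: int = 3
    max_gap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if self.span_min < 0:
            raise ValueError("span_min must be >= 0")
        if not (0.0 <= self.variable_fraction_max <= 1.0):
            raise ValueError("variable_fraction_max must be in [0, 1]")
        if self.max_contiguous_variable < 0:
            raise ValueError("max_contiguous_variable must be >= 0")
        if self.max_gap is not None and self.max_gap < 1:
            raise ValueError("max_gap must be >= 1 when set")


@dataclass(frozen=True)
class SweepRegion:
    """A called sweep: one population, one chromosome, a run of loci.

    ``fixed_haplotype`` holds the major allele at each fixed locus and
    :data:`VARIABLE_SENTINEL` at loci counted in ``n_variable``; it is the
    vector compared across populations at shared core loci.  ``locus_ids``
    and ``fixed_haplotype`` are ``None`` for regions transcribed from
    published coordinate tables.
    """

    population: str
    chrom: str
    start: int
    end: int
    n_total: int
    n_fixed: int
    n_variable: int
    locus_ids: Optional[tuple[str, ...]] = None
    fixed_haplotype: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region start {self.start} must be < end {self.end}")
        if self.n_total != self.n_fixed + self.n_variable:
            raise ValueError("n_total must equal n_fixed + n_variable")
        if self.locus_ids is not None and len(self.locus_ids) != self.n_total:
            raise ValueError("locus_ids length must equal n_total")
        if self.fixed_haplotype is not None and len(self.fixed_haplotype) != self.n_total:
            raise ValueError("fixed_haplotype length must equal n_total")

    @property
    def size(self) -> int:
        """``end - start`` in bp."""
        return region_size(self.start, self.end)


def _sort_regions(regions: list[SweepRegion]) -> list[SweepRegion]:
    return sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end))


def _major_allele(f_alt: float, ref: str, alt: str) -> str:
    # tie (f_alt == 0.5) can only arise at M = 1; resolve toward ref
    return alt if f_alt > 0.5 else ref


def _run_boundaries(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i, j) bounds of maximal True runs of a boolean vector."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts, ends))


def _split_at_gaps(
    i: int, j: int, pos: np.ndarray, max_gap: Optional[int]
) -> list[tuple[int, int]]:
    if max_gap is None:
        return [(i, j)]
    out: list[tuple[int, int]] = []
    start = i
    for k in range(i + 1, j):
        if pos[k] - pos[k - 1] > max_gap:
            out.append((start, k))
            start = k
    out.append((start, j))
    return out


# ---------------------------------------------------------------------------
# Low-density scan
# ---------------------------------------------------------------------------

def scan_low_density(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    params: LowDensityScanParams = LowDensityScanParams(),
) -> list[SweepRegion]:
    """Maximal runs of loci with MAF <= ``maf_max`` meeting length and span.

    Loci with no called genotype in the population have an undefined MAF and
    break runs.  ``n_variable`` counts run loci with 0 < MAF <= ``maf_max``
    (residual variation tolerated inside a completed sweep); strictly
    monomorphic loci contribute the observed allele to ``fixed_haplotype``.
    """
    if matrix.n_loci == 0:
        return []
    f_alt = alt_frequency_vector(matrix, panel, population)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(f_alt, 1.0 - f_alt)
        low = np.nan_to_num(maf, nan=np.inf) <= params.maf_max

    smap = matrix.snp_map
    regions: list[SweepRegion] = []
    for chrom in smap.chromosomes:
        sl = smap.chrom_slice(chrom)
        pos = smap.pos[sl]
        for i0, j0 in _run_boundaries(low[sl]):
            for i, j in _split_at_gaps(i0, j0, pos, params.max_gap):
                n = j - i
                span = int(pos[j - 1] - pos[i])
                if n < params.n_min or span < params.span_min:
                    continue
                idx = np.arange(sl.start + i, sl.start + j)
                run_maf = maf[idx]
                n_var = int(np.sum(run_maf > 0.0))
                hap = tuple(
                    _major_allele(f_alt[k], str(smap.ref[k]), str(smap.alt[k]))
                    if maf[k] == 0.0
                    else VARIABLE_SENTINEL
                    for k in idx
                )
                regions.append(
                    SweepRegion(
                        population=population,
                        chrom=chrom,
                        start=int(pos[i]),
                        end=int(pos[j - 1]),
                        n_total=n,
                        n_fixed=n - n_var,
                        n_variable=n_var,
                        locus_ids=tuple(smap.ids[k] for k in idx),
                        fixed_haplotype=hap,
                    )
                )
    return _sort_regions(regions)


# ---------------------------------------------------------------------------
# High-density scan
# ---------------------------------------------------------------------------

def classify_variable(
    matrix: GenotypeMatrix, panel: PopulationPanel, population: str
) -> np.ndarray:
    """Float vector: 1.0 = variable (MAF > 1/(2M)), 0.0 = fixed, NaN = no data."""
    f_alt = alt_frequency_vector(matrix, panel, population)
    m = n_called_vector(matrix, panel, population)
    out = np.full(matrix.n_loci, np.nan)
    called = m > 0
    with np.errstate(invalid="ignore"):
        maf = np.minimum(f_alt, 1.0 - f_alt)
        out[called] = (maf[called] > 1.0 / (2.0 * m[called])).astype(float)
    return out


def _emit_hd_segment(
    seg: np.ndarray,
    var: np.ndarray,
    pos: np.ndarray,
    params: HighDensityScanParams,
) -> list[tuple[int, int]]:
    """Greedy left-to-right delimitation within one admissible segment.

    ``seg`` holds absolute locus indices of a stretch whose boundary loci are
    fixed and whose interior variable runs are all <= max_contiguous_variable.
    Candidate right ends are the last fixed locus before each variable run
    (and the segment end); from each anchor the longest candidate whose
    whole-interval variable fraction passes is taken.  On failure the anchor
    advances past the next variable run, so admissible intervals that start
    after a variable-heavy prefix are still found.
    """
    n = seg.size
    v = var[seg].astype(bool)
    cum = np.concatenate(([0], np.cumsum(v)))  # variable count in seg[:k]
    # right-end candidates: index of last fixed locus before each variable run,
    # plus the final fixed locus of the segment
    var_run_starts = [k for k in range(n) if v[k] and (k == 0 or not v[k - 1])]
    out: list[tuple[int, int]] = []
    a = 0
    while a < n:
        if v[a]:
            a += 1
            continue
        # candidate ends >= a: last fixed before each variable run after a, and n-1
        cands = [rs - 1 for rs in var_run_starts if rs - 1 >= a] + [n - 1]
        cands = sorted({c for c in cands if c >= a and not v[c]}, reverse=True)
        chosen = None
        for b in cands:
            n_tot = b - a + 1
            n_var = int(cum[b + 1] - cum[a])
            if n_var <= params.variable_fraction_max * n_tot:
                chosen = b
                break
        if chosen is None:  # lone fixed anchor surrounded by variable runs
            a += 1
            continue
        n_tot = chosen - a + 1
        span = int(pos[seg[chosen]] - pos[seg[a]])
        if n_tot >= params.n_min and span >= params.span_min:
            out.append((a, chosen))
            a = chosen + 1
        else:
            # advance past the next variable run (a later anchor may admit a
            # longer clean stretch); if none, the segment is exhausted
            nxt = next((rs for rs in var_run_starts if rs > a), None)
            if nxt is None:
                break
            a = nxt + 1
    return [(int(seg[i]), int(seg[j])) for i, j in out]


def scan_high_density(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    params: HighDensityScanParams = HighDensityScanParams(),
) -> list[SweepRegion]:
    """Disjoint regions satisfying the count/span/fraction/contiguity rules.

    Delimitation is deterministic left-to-right greedy (see
    ``docs/methods.md``): chromosomes are cut at unclassifiable loci and at
    variable runs longer than ``max_contiguous_variable``; within each
    remaining segment the longest admissible interval from each anchor is
    emitted. Boundary loci of every region are fixed.
    """
    if matrix.n_loci == 0:
        return []
    var = classify_variable(matrix, panel, population)
    f_alt = alt_frequency_vector(matrix, panel, population)
    smap = matrix.snp_map
    regions: list[SweepRegion] = []
    for chrom in smap.chromosomes:
        sl = smap.chrom_slice(chrom)
        pos = smap.pos
        v = var[sl]
        # admissible loci: classified, and not inside an over-long variable run
        ok = ~np.isnan(v)
        for i, j in _run_boundaries(np.nan_to_num(v, nan=1.0) == 1.0):
            if j - i > params.max_contiguous_variable:
                ok[i:j] = False
        for i0, j0 in _run_boundaries(ok):
            for i, j in _split_at_gaps(i0, j0, smap.pos[sl], params.max_gap):
                seg = np.arange(sl.start + i, sl.start + j)
                # trim boundary variable loci
                vb = var[seg] == 1.0
                nz = np.flatnonzero(~vb)
                if nz.size == 0:
                    continue
                seg = seg[nz[0]: nz[-1] + 1]
                for a, b in _emit_hd_segment(seg, var, pos, params):
                    idx = np.arange(a, b + 1)
                    n_var = int(np.sum(var[idx] == 1.0))
                    hap = tuple(
                        _major_allele(f_alt[k], str(smap.ref[k]), str(smap.alt[k]))
                        if var[k] == 0.0
                        else VARIABLE_SENTINEL
                        for k in idx
                    )
                    regions.append(
                        SweepRegion(
                            population=population,
                            chrom=chrom,
                            start=int(pos[a]),
                            end=int(pos[b]),
                            n_total=idx.size,
                            n_fixed=idx.size - n_var,
                            n_variable=n_var,
                            locus_ids=tuple(smap.ids[k] for k in idx),
                            fixed_haplotype=hap,
                        )
                    )
    return _sort_regions(regions)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def regions_to_frame(regions: Sequence[SweepRegion]) -> pd.DataFrame:
    """TSV-ready table (population, chrom, start, end, SNP counts, size)."""
    return pd.DataFrame(
        {
            "population": [r.population for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_total": [r.n_total for r in regions],
            "n_fixed": [r.n_fixed for r in regions],
            "n_variable": [r.n_variable for r in regions],
            "size": [r.size for r in regions],
        }
    )


def regions_to_bed(regions: Sequence[SweepRegion]) -> pd.DataFrame:
    """BED3+ frame (0-based half-open; BED length = size + 1 by convention)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.end for r in regions],
            "name": [f"{r.population}:{r.n_total}snp" for r in regions],
        }
    )
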