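"""Data model for SNP maps, diploid genotype matrices and population panels.

The genomic axis of every sweep scan is a :class:`SnpMap`: an ordered list of
biallelic markers grouped by chromosome with strictly increasing base-pair
positions.  "Contiguous SNPs" always means adjacent in map order *after*
filtering, so scans operate on whatever loci survive the call-rate and
chromosome filters defined here.

Genotypes are stored as a dense ``int8`` matrix of per-(locus, sample) codes:
``0`` = reference homozygote, ``1`` = heterozygote, ``2`` = alternate
homozygote, ``-1`` = missing.  Missingness is an explicit state and is never
imputed: minor-allele frequencies are computed from called alleles only, in
both numerator and denominator, which matches the ``(2M)^-1`` heterozygote
bound used by the high-density scan (``M`` = individuals with genotypes at the
locus).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
"""Sentinel genotype code for a missing call."""


class NoDataError(ValueError):
    """Raised when an allele frequency is requested where no calls exist.

    Distinct from a MAF of 0: a monomorphic locus has data, a no-data locus
    has an undefined frequency.
    """


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural sort key for chromosome labels: numeric first, then X/Y/etc."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class SnpLocus:
    """A single biallelic marker on the reference assembly (1-based)."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus {self.id}: position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"locus {self.id}: ref and alt alleles are identical")


class SnpMap:
    """Ordered marker coordinates; adjacency in this order defines contiguity.

    Loci must be grouped by chromosome with strictly increasing positions
    within each chromosome; duplicate (chrom, pos) pairs are rejected.
    Chromosome order is the order of first appearance (readers sort labels
    naturally before construction).
    """

    def __init__(self, loci: Sequence[SnpLocus]):
        self.ids: list[str] = [l.id for l in loci]
        self.chroms: np.ndarray = np.asarray([l.chrom for l in loci], dtype=object)
        self.pos: np.ndarray = np.asarray([l.pos for l in loci], dtype=np.int64)
        self.ref: np.ndarray = np.asarray([l.ref_allele for l in loci], dtype=object)
        self.alt: np.ndarray = np.asarray([l.alt_allele for l in loci], dtype=object)
        self._chrom_slices: dict[str, slice] = {}
        self._validate()

    @classmethod
    def from_arrays(
        cls,
        ids: Sequence[str],
        chroms: Sequence[str],
        pos: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[str],
    ) -> "SnpMap":
        obj = cls.__new__(cls)
        obj.ids = list(ids)
        obj.chroms = np.asarray(chroms, dtype=object)
        obj.pos = np.asarray(pos, dtype=np.int64)
        obj.ref = np.asarray(ref, dtype=object)
        obj.alt = np.asarray(alt, dtype=object)
        obj._chrom_slices = {}
        obj._validate()
        return obj

    def _validate(self) -> None:
        n = len(self.ids)
        if not (len(self.chroms) == len(self.pos) == len(self.ref) == len(self.alt) == n):
            raise ValueError("SnpMap arrays have inconsistent lengths")
        if np.any(self.pos < 1):
            raise ValueError("positions must be >= 1")
        start = 0
        seen: set[str] = set()
        for i in range(1, n + 1):
            if i == n or self.chroms[i] != self.chroms[start]:
                chrom = str(self.chroms[start])
                if chrom in seen:
                    raise ValueError(f"chromosome {chrom!r} is not contiguous in map order")
                seen.add(chrom)
                block = self.pos[start:i]
                if np.any(np.diff(block) <= 0):
                    raise ValueError(
                        f"positions on chromosome {chrom!r} must be strictly increasing "
                        "(duplicates or unsorted input)"
                    )
                self._chrom_slices[chrom] = slice(start, i)
                start = i

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, i: int) -> SnpLocus:
        return SnpLocus(self.ids[i], str(self.chroms[i]), int(self.pos[i]),
                        str(self.ref[i]), str(self.alt[i]))

    def __iter__(self) -> Iterator[SnpLocus]:
        for i in range(len(self)):
            yield self[i]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order."""
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        """Index slice covering all loci on ``chrom``."""
        return self._chrom_slices[chrom]

    def subset(self, index: np.ndarray) -> "SnpMap":
        """New map keeping loci at ``index`` (order preserved)."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SnpMap.from_arrays(
            [self.ids[i] for i in idx],
            self.chroms[idx], self.pos[idx], self.ref[idx], self.alt[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "chrom": self.chroms, "pos": self.pos,
             "ref": self.ref, "alt": self.alt}
        )


class GenotypeMatrix:
    """Diploid calls for every (locus, sample) pair.

    Parameters
    ----------
    snp_map
        Marker axis; row ``i`` of ``calls`` belongs to ``snp_map[i]``.
    samples
        Ordered, unique sample identifiers (columns of ``calls``).
    calls
        ``int8`` array of shape (n_loci, n_samples) with codes
        {0, 1, 2, MISSING}.
    """

    def __init__(self, snp_map: SnpMap, samples: Sequence[str], calls: np.ndarray):
        self.snp_map = snp_map
        self.samples: list[str] = list(samples)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(snp_map), len(self.samples)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(snp_map)} loci x {len(self.samples)} samples"
            )
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.calls = calls

    @property
    def n_loci(self) -> int:
        return len(self.snp_map)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def subset_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(self.snp_map.subset(idx), self.samples,
                              self.calls[idx].copy())

    def locus_index_by_id(self) -> dict[str, int]:
        return {lid: i for i, lid in enumerate(self.snp_map.ids)}


class PopulationPanel:
    """Sample-to-population assignment (each sample has exactly one label)."""

    def __init__(self, assignment: Mapping[str, str]):
        if not assignment:
            raise ValueError("empty population assignment")
        self.assignment: dict[str, str] = dict(assignment)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignment.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_for(self, population: str) -> list[str]:
        out = [s for s, p in self.assignment.items() if p == population]
        if not out:
            raise KeyError(f"population {population!r} has no samples")
        return out

    def column_indices(self, matrix: GenotypeMatrix, population: str) -> np.ndarray:
        members = set(self.samples_for(population))
        idx = np.asarray([i for i, s in enumerate(matrix.samples) if s in members],
                         dtype=np.intp)
        if idx.size == 0:
            raise KeyError(f"population {population!r} has no samples in this matrix")
        return idx

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        missing = [s for s in matrix.samples if s not in self.assignment]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))


# ---------------------------------------------------------------------------
# Allele-frequency computation
# ---------------------------------------------------------------------------

def allele_counts(
    matrix: GenotypeMatrix, columns: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (alt-allele count, called-individual count) over ``columns``."""
    sub = matrix.calls[:, columns]
    called = sub != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    return alt.astype(np.int64), n_called.astype(np.int64)


def alt_frequency_vector(
    matrix: GenotypeMatrix, panel: PopulationPanel, population: str
) -> np.ndarray:
    """Alternate-allele frequency per locus; NaN where no calls exist."""
    cols = panel.column_indices(matrix, population)
    alt, n_called = allele_counts(matrix, cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return f


def maf_vector(
    matrix: GenotypeMatrix, panel: PopulationPanel, population: str
) -> np.ndarray:
    """Folded (minor) allele frequency per locus in [0, 0.5]; NaN = no data."""
    f = alt_frequency_vector(matrix, panel, population)
    return np.minimum(f, 1.0 - f)


def n_called_vector(
    matrix: GenotypeMatrix, panel: PopulationPanel, population: str
) -> np.ndarray:
    """Number of individuals with genotypes (M) per locus in the population."""
    cols = panel.column_indices(matrix, population)
    return (matrix.calls[:, cols] != MISSING).sum(axis=1).astype(np.int64)


def compute_maf(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    locus_index: int,
) -> float:
    """MAF of one locus in one population, from called alleles only.

    Raises
    ------
    NoDataError
        If every call at the locus is missing within the population.
    """
    cols = panel.column_indices(matrix, population)
    row = matrix.calls[locus_index, cols]
    called = row != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise NoDataError(
            f"locus index {locus_index}: no called genotypes in {population!r}"
        )
    f = int(row[called].sum()) / (2.0 * n_called)
    return min(f, 1.0 - f)


def variable_maf_threshold(population_size_called: int) -> float:
    """Heterozygote bound 1/(2M) for a locus called in M diploid individuals.

    A locus with exactly one heterozygote among M called individuals has MAF
    equal to (not exceeding) this threshold, so a single heterozygote — the
    allowance made for genotyping error — does not mark a locus variable.
    """
    if population_size_called < 1:
        raise ValueError("M must be >= 1")
    return 1.0 / (2.0 * population_size_called)


# ---------------------------------------------------------------------------
# Locus filters
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    """A filtered matrix plus a removal report (locus id, reason)."""

    matrix: GenotypeMatrix
    report: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["locus_id", "reason"])
    )


def call_rate_filter(
    matrix: GenotypeMatrix,
    panel: Optional[PopulationPanel] = None,
    overall_min: float = 0.85,
    within_population_min: Optional[float] = None,
) -> FilterResult:
    """Drop loci below the overall and (optionally) per-population call rate.

    ``overall_min`` applies to the non-missing fraction across all samples;
    ``within_population_min`` (requires ``panel``) must be met in *every*
    population. Genotype codes of retained loci are unchanged.
    """
    if matrix.n_loci == 0 or matrix.n_samples == 0:
        raise ValueError("cannot filter an empty genotype matrix")
    for thr in (overall_min, within_population_min):
        if thr is not None and not (0.0 <= thr <= 1.0):
            raise ValueError(f"call-rate threshold {thr} outside [0, 1]")

    called = matrix.calls != MISSING
    overall = called.mean(axis=1)
    keep = overall >= overall_min
    reasons: dict[int, str] = {
        i: f"overall_call_rate={overall[i]:.4f}<{overall_min}"
        for i in np.flatnonzero(~keep)
    }
    if within_population_min is not None:
        if panel is None:
            raise ValueError("within_population_min requires a population panel")
        for pop in panel.populations:
            cols = panel.column_indices(matrix, pop)
            rate = called[:, cols].mean(axis=1)
            low = rate < within_population_min
            for i in np.flatnonzero(low & keep):
                reasons.setdefault(
                    int(i),
                    f"call_rate[{pop}]={rate[i]:.4f}<{within_population_min}",
                )
            keep &= ~low
    report = pd.DataFrame(
        {"locus_id": [matrix.snp_map.ids[i] for i in sorted(reasons)],
         "reason": [reasons[i] for i in sorted(reasons)]}
    )
    return FilterResult(matrix.subset_loci(keep), report)


def exclude_chromosomes(
    matrix: GenotypeMatrix, labels: Iterable[str]
) -> GenotypeMatrix:
    """Remove every locus on the given chromosomes (order preserved).

    Used to drop X-linked loci, whose assembly quality and hemizygosity in
    male panels make allele-frequency estimates unreliable.
    """
    labels = set(labels)
    keep = ~np.isin(matrix.snp_map.chroms.astype(str), list(labels))
    return matrix.subset_loci(keep)


@dataclass(frozen=True)
class LowMafSummary:
    """Fraction of loci at or below a MAF bound, and the monomorphic count."""

    fraction: float
    n_low: int
    n_monomorphic: int
    n_loci: int


def low_maf_fraction(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    maf_max: float = 0.0,
) -> LowMafSummary:
    """Fraction of loci with MAF <= ``maf_max`` in one population.

    With ``maf_max = 0`` this is the monomorphic fraction — the per-SNP
    probability ``q`` that drives the analytic false-positive model. Loci with
    no called genotypes in the population are counted as neither low nor
    monomorphic (their MAF is undefined) but remain in the denominator.
    """
    if matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    maf = maf_vector(matrix, panel, population)
    with np.errstate(invalid="ignore"):
        n_low = int(np.nansum(maf <= maf_max))
        n_mono = int(np.nansum(maf == 0.0))
    return LowMafSummary(n_low / matrix.n_loci, n_low, n_mono, matrix.n_loci)
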