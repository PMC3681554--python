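"""Analytic type-I-error arithmetic for the contiguous-run sweep scan.

If a fraction ``q`` of SNPs is monomorphic within a population and loci are
treated as independent, the probability that ``N`` map-adjacent SNPs are all
monomorphic is ``q^N``.  Scanning ``S`` SNPs spread over ``C`` chromosomes
offers ``S - C*(N - 1)`` placements for an ``N``-SNP window (each chromosome
loses ``N - 1`` window starts at its end; telomere/centromere effects are
otherwise ignored), so the expected number of windows of ``N`` contiguous
fixed-allele SNPs arising by chance is::

    E[FP](N) = q^N * (S - C*(N - 1))

Raising ``N`` suppresses this expectation geometrically but also raises the
smallest detectable sweep to roughly ``(N - 1)`` median marker intervals —
the trade-off that motivates breed-specific run lengths on ascertainment-
biased panels (breeds far from the SNP-discovery breeds have larger ``q``).

The expectation counts *windows*: a maximal run of ``L >= N`` qualifying loci
contains ``L - N + 1`` such windows.  Empirical cross-checks against the
scanner should therefore count windows, not maximal runs (see
``docs/methods.md``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ScanErrorModel:
    """(q, S, C): per-SNP low-MAF probability, SNP count, chromosome count."""

    q: float
    S: int
    C: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q must be in [0, 1]")
        if not self.S > self.C >= 1:
            raise ValueError("require S > C >= 1")

    def n_positions(self, N: int) -> int:
        """Number of placements for an N-SNP window: S - C*(N-1)."""
        if N < 1:
            raise ValueError("N must be >= 1")
        return self.S - self.C * (N - 1)


def expected_false_positive_regions(model: ScanErrorModel, N: int) -> float:
    """Expected count of chance windows of N contiguous low-MAF SNPs.

    Returns 0 (with a warning) when N is so large that no window fits.
    """
    positions = model.n_positions(N)
    if positions <= 0:
        warnings.warn(
            f"N={N} leaves no testable window position (S={model.S}, C={model.C})",
            stacklevel=2,
        )
        return 0.0
    return model.q ** N * positions


def recommend_run_length(
    model: ScanErrorModel, max_expected_fp: float, n_floor: int = 5
) -> int:
    """Smallest N >= ``n_floor`` with E[FP](N) <= ``max_expected_fp``.

    Advisory only: the run length is a user-visible, population-specific
    parameter; this helper operationalises the type-I-error side of the
    trade-off (the detectable-span side is :func:`expected_detectable_span`).
    Monotone non-decreasing in q.
    """
    if max_expected_fp <= 0:
        raise ValueError("max_expected_fp must be > 0")
    n = max(1, n_floor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while expected_false_positive_regions(model, n) > max_expected_fp:
            n += 1
    return n


def cross_breed_overlap_probability(S: int, C: int, N: int) -> float:
    """Chance that one false-positive N-SNP run in each of two populations
    overlaps by at least one SNP anywhere in the genome.

    With ``P = S - C*(N - 1)`` equally likely placements per population, a
    placed run overlaps a fixed one at ``w = 2N - 1`` of the P positions, so
    the probability is ``P * (1/P * w/P) = w/P`` (chromosome-end effects
    ignored).  Near-nil values are why a sweep called in two or more
    populations is effectively self-validating.
    """
    positions = S - C * (N - 1)
    if positions <= 0:
        raise ValueError("S - C*(N-1) must be > 0")
    return (2 * N - 1) / positions


def expected_detectable_span(N: int, median_interval: int) -> float:
    """Average span of N adjacent markers: (N - 1) * median inter-marker gap."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return (N - 1) * median_interval


def expectation_table(
    model: ScanErrorModel, n_min: int = 2, n_max: int = 12, median_interval: int = 37_000
) -> pd.DataFrame:
    """E[FP], window positions and detectable span for a range of N."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for n in range(n_min, n_max + 1):
            rows.append(
                {
                    "N": n,
                    "positions": model.n_positions(n),
                    "expected_false_positives": expected_false_positive_regions(model, n),
                    "detectable_span_bp": expected_detectable_span(n, median_interval),
                }
            )
    return pd.DataFrame(rows)
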