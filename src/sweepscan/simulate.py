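"""Synthetic genotype panels with the structure the sweep scans assume.

The generator emulates what matters to a contiguous low-MAF run scan on an
ascertainment-biased SNP array:

* an assay-like map — positions drawn per chromosome with exponential gaps
  whose median matches the target inter-marker interval (~37 kb for 50K-like
  panels, ~975 bp for HD-like panels);
* a per-population folded-Beta MAF spectrum with a point mass of monomorphic
  loci (``low_maf_fraction``), the knob that mimics ascertainment bias —
  populations far from the SNP-discovery breeds show monomorphic fractions of
  roughly 12-25%;
* missing calls and symmetric genotyping error (default rate 0.5%);
* planted completed sweeps: intervals fixed for one haplotype shared by the
  listed populations, with optional residual per-locus heterozygotes standing
  in for new mutation and residual error.

Loci are simulated independently (no linkage disequilibrium), matching the
independence assumption of the analytic false-positive model; see
``docs/methods.md`` for what that does and does not exercise.  Output is a
pure function of the configuration, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .genotype_model import MISSING, GenotypeMatrix, PopulationPanel, SnpMap

__all__ = [
    "PopulationSpec",
    "PlantedSweep",
    "SimulationConfig",
    "SimulationResult",
    "simulate_panel",
    "make_table_fixture",
    "calibrate_low_maf_fraction",
    "snp50_config",
    "hd_config",
    "truth_to_bed",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One population: size, monomorphic point mass, folded-Beta spectrum.

    The segregating-MAF spectrum is ``0.5 * Beta(beta_a, beta_b)`` on
    (0, 0.5]; the defaults give a uniform folded spectrum, a reasonable
    stand-in for a common-SNP array.
    """

    label: str
    n_samples: int
    low_maf_fraction: float = 0.15
    beta_a: float = 1.0
    beta_b: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0.0 <= self.low_maf_fraction <= 1.0):
            raise ValueError("low_maf_fraction must be in [0, 1]")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta shape parameters must be > 0")


@dataclass(frozen=True)
class PlantedSweep:
    """A completed sweep planted into one or more populations."""

    populations: frozenset[str]
    chrom: str
    start: int
    end: int
    residual_variation_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", frozenset(self.populations))
        if self.start >= self.end:
            raise ValueError("planted sweep start must be < end")
        if not (0.0 <= self.residual_variation_rate <= 1.0):
            raise ValueError("residual_variation_rate must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic panel (a pure function of this)."""

    seed: int
    populations: tuple[PopulationSpec, ...]
    n_chromosomes: int = 29
    n_snps: int = 52_942
    median_interval: int = 37_000
    chromosome_length: Optional[int] = None
    missing_rate: float = 0.02
    genotyping_error_rate: float = 0.005
    planted_sweeps: tuple[PlantedSweep, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "planted_sweeps", tuple(self.planted_sweeps))
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.median_interval < 1:
            raise ValueError("median_interval must be >= 1")
        for rate in (self.missing_rate, self.genotyping_error_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        chroms = {str(c) for c in range(1, self.n_chromosomes + 1)}
        for sweep in self.planted_sweeps:
            unknown = sweep.populations - set(labels)
            if unknown:
                raise ValueError(f"planted sweep references unknown populations {unknown}")
            if sweep.chrom not in chroms:
                raise ValueError(f"planted sweep references unknown chromosome {sweep.chrom!r}")
            if self.chromosome_length is not None and sweep.end > self.chromosome_length:
                raise ValueError("planted sweep extends past chromosome_length")


def snp50_config(
    populations: Sequence[PopulationSpec],
    seed: int = 0,
    n_snps: int = 52_942,
    **overrides,
) -> SimulationConfig:
    """50K-like profile: 29 autosomes, median spacing 37 kb."""
    overrides.setdefault("n_chromosomes", 29)
    overrides.setdefault("median_interval", 37_000)
    return SimulationConfig(
        seed=seed, populations=tuple(populations), n_snps=n_snps, **overrides,
    )


def hd_config(
    populations: Sequence[PopulationSpec],
    seed: int = 0,
    n_snps: int = 2_575_339,
    **overrides,
) -> SimulationConfig:
    """HD-like profile: 29 autosomes, median spacing 975 bp."""
    overrides.setdefault("n_chromosomes", 29)
    overrides.setdefault("median_interval", 975)
    return SimulationConfig(
        seed=seed, populations=tuple(populations), n_snps=n_snps, **overrides,
    )


@dataclass
class SimulationResult:
    matrix: GenotypeMatrix
    panel: PopulationPanel
    truth: tuple[PlantedSweep, ...]


def calibrate_low_maf_fraction(
    target_q: float, n_samples: int, beta_a: float = 1.0, beta_b: float = 1.0
) -> float:
    """Monomorphic point mass whose *realized* monomorphic rate is ``target_q``.

    A segregating locus with folded MAF ``m`` is still drawn monomorphic in a
    sample of M diploids with probability ``m^(2M) + (1 - m)^(2M)``; solving
    ``p0 + (1 - p0) * eps = target_q`` for the point mass ``p0`` removes that
    finite-sample inflation, with ``eps`` the spectrum expectation of
    sample-monomorphism computed by quadrature.
    """
    k = 2 * n_samples
    pdf = stats.beta(beta_a, beta_b).pdf

    def integrand(x: float) -> float:
        return pdf(x) * ((x / 2.0) ** k + (1.0 - x / 2.0) ** k)

    eps, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    if eps >= target_q:
        return 0.0
    return (target_q - eps) / (1.0 - eps)


def _draw_positions(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[list[str], np.ndarray, dict[str, slice]]:
    base, extra = divmod(config.n_snps, config.n_chromosomes)
    chroms: list[str] = []
    pos_parts: list[np.ndarray] = []
    slices: dict[str, slice] = {}
    offset = 0
    for c in range(1, config.n_chromosomes + 1):
        n_i = base + (1 if c <= extra else 0)
        if n_i == 0:
            continue
        if config.chromosome_length is None:
            gaps = rng.exponential(config.median_interval / math.log(2.0), n_i)
            pos = np.cumsum(np.maximum(1, np.round(gaps)).astype(np.int64))
        else:
            pos = np.sort(
                rng.choice(config.chromosome_length, size=n_i, replace=False)
            ).astype(np.int64) + 1
        label = str(c)
        chroms.extend([label] * n_i)
        pos_parts.append(pos)
        slices[label] = slice(offset, offset + n_i)
        offset += n_i
    return chroms, np.concatenate(pos_parts), slices


def simulate_panel(config: SimulationConfig) -> SimulationResult:
    """Generate (matrix, panel, ground truth) from a configuration.

    Draw order is fixed (map, then per-population frequencies and genotypes,
    then planted sweeps, then error, then missingness), so identical
    configurations give byte-identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    chroms, pos, chrom_slices = _draw_positions(rng, config)
    n_loci = len(chroms)
    ids = [f"snp_{c}_{p}" for c, p in zip(chroms, pos)]
    snp_map = SnpMap.from_arrays(ids, chroms, pos, ["A"] * n_loci, ["G"] * n_loci)

    samples: list[str] = []
    assignment: dict[str, str] = {}
    call_blocks: list[np.ndarray] = []
    col_slices: dict[str, slice] = {}
    col = 0
    for spec in config.populations:
        names = [f"{spec.label}_{i:04d}" for i in range(spec.n_samples)]
        samples.extend(names)
        assignment.update({s: spec.label for s in names})
        mono = rng.random(n_loci) < spec.low_maf_fraction
        m = 0.5 * rng.beta(spec.beta_a, spec.beta_b, n_loci)
        flip = rng.random(n_loci) < 0.5
        f = np.where(flip, m, 1.0 - m)
        mono_allele = rng.integers(0, 2, n_loci).astype(float)
        f = np.where(mono, mono_allele, f)
        calls = rng.binomial(2, f[:, None], size=(n_loci, spec.n_samples)).astype(np.int8)
        call_blocks.append(calls)
        col_slices[spec.label] = slice(col, col + spec.n_samples)
        col += spec.n_samples
    calls = np.concatenate(call_blocks, axis=1)

    pop_order = [p.label for p in config.populations]
    for sweep in config.planted_sweeps:
        sl = chrom_slices[sweep.chrom]
        in_sweep = np.flatnonzero(
            (pos[sl] >= sweep.start) & (pos[sl] <= sweep.end)
        ) + sl.start
        hap = rng.integers(0, 2, in_sweep.size).astype(np.int8)  # shared haplotype
        for label in pop_order:
            if label not in sweep.populations:
                continue
            cols = col_slices[label]
            calls[np.ix_(in_sweep, np.arange(cols.start, cols.stop))] = (2 * hap)[:, None]
            if sweep.residual_variation_rate > 0:
                resid = rng.random(in_sweep.size) < sweep.residual_variation_rate
                which = rng.integers(cols.start, cols.stop, in_sweep.size)
                for locus, sample in zip(in_sweep[resid], which[resid]):
                    calls[locus, sample] = 1

    if config.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < config.genotyping_error_rate
        shift = rng.integers(1, 3, calls.shape, dtype=np.int8)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls = np.where(miss, np.int8(MISSING), calls)

    matrix = GenotypeMatrix(snp_map, samples, calls)
    return SimulationResult(matrix, PopulationPanel(assignment), config.planted_sweeps)


def truth_to_bed(truth: Sequence[PlantedSweep]) -> pd.DataFrame:
    """Ground-truth intervals as a BED3+ frame (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in truth],
            "start": [s.start - 1 for s in truth],
            "end": [s.end for s in truth],
            "name": [",".join(sorted(s.populations)) for s in truth],
        }
    )


# ---------------------------------------------------------------------------
# Deterministic fixtures reproducing published table rows
# ---------------------------------------------------------------------------

def make_table_fixture(
    rows: Sequence[tuple[str, int, int, int, int]],
    population: str,
    samples: int,
    n_het_variable: int = 2,
    flank_loci: int = 3,
    flank_gap: int = 10_000,
) -> tuple[GenotypeMatrix, PopulationPanel]:
    """Panel in which each (chrom, start, end, n_total, n_variable) row is a
    detectable sweep with exactly the stated geometry, flanked by high-MAF loci.

    Region loci sit at evenly spaced positions with the first at ``start`` and
    the last at ``end``; the ``n_variable`` variable loci are isolated interior
    loci carrying ``n_het_variable`` heterozygotes each (2 makes a locus
    variable under the 1/(2M) rule; 1 keeps MAF at exactly the threshold).
    Inconsistent rows — counts that cannot fit the interval, variable loci
    that cannot be isolated, or rows whose flanks would collide — are
    rejected.
    """
    if samples < 2:
        raise ValueError("need >= 2 samples so flanking loci can be polymorphic")
    if not (0 <= n_het_variable <= samples):
        raise ValueError("n_het_variable must be in [0, samples]")

    half = samples // 2
    flank_call = np.zeros(samples, dtype=np.int8)
    flank_call[:half] = 2  # alt-allele frequency ~0.5: unambiguously variable

    by_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for chrom, start, end, n_total, n_variable in rows:
        if start >= end:
            raise ValueError(f"row {chrom}:{start}-{end}: start must be < end")
        if not (0 <= n_variable <= n_total - 2) or n_total < 2:
            raise ValueError(
                f"row {chrom}:{start}-{end}: inconsistent counts "
                f"(n_total={n_total}, n_variable={n_variable})"
            )
        by_chrom.setdefault(str(chrom), []).append((start, end, n_total, n_variable))

    loci_chrom: list[str] = []
    loci_pos: list[int] = []
    loci_calls: list[np.ndarray] = []

    from .genotype_model import chrom_sort_key

    for chrom in sorted(by_chrom, key=chrom_sort_key):
        entries = sorted(by_chrom[chrom])
        prev_end = None
        for start, end, n_total, n_variable in entries:
            margin = flank_loci * flank_gap
            if start - margin < 1:
                raise ValueError(f"row {chrom}:{start}-{end}: flank extends below 1")
            if prev_end is not None and start - margin <= prev_end + margin:
                raise ValueError(f"rows on chromosome {chrom} too close for flanks")
            positions = np.round(np.linspace(start, end, n_total)).astype(np.int64)
            positions[0], positions[-1] = start, end
            if np.any(np.diff(positions) <= 0):
                raise ValueError(
                    f"row {chrom}:{start}-{end}: {n_total} loci do not fit the span"
                )
            var_idx = {
                int(round((k + 1) * (n_total - 1) / (n_variable + 1)))
                for k in range(n_variable)
            }
            if (
                len(var_idx) != n_variable
                or any(i <= 0 or i >= n_total - 1 for i in var_idx)
                or any(i + 1 in var_idx for i in var_idx)
            ):
                raise ValueError(
                    f"row {chrom}:{start}-{end}: cannot isolate {n_variable} "
                    f"variable loci among {n_total}"
                )
            # leading flank
            for k in range(flank_loci, 0, -1):
                loci_chrom.append(chrom)
                loci_pos.append(start - k * flank_gap)
                loci_calls.append(flank_call.copy())
            for i, p in enumerate(positions):
                loci_chrom.append(chrom)
                loci_pos.append(int(p))
                call = np.full(samples, 0 if i % 2 == 0 else 2, dtype=np.int8)
                if i in var_idx:
                    call[:] = 0
                    call[:n_het_variable] = 1
                loci_calls.append(call)
            # trailing flank
            for k in range(1, flank_loci + 1):
                loci_chrom.append(chrom)
                loci_pos.append(end + k * flank_gap)
                loci_calls.append(flank_call.copy())
            prev_end = end + flank_loci * flank_gap

    ids = [f"fx_{c}_{p}" for c, p in zip(loci_chrom, loci_pos)]
    snp_map = SnpMap.from_arrays(
        ids, loci_chrom, loci_pos, ["A"] * len(ids), ["G"] * len(ids)
    )
    sample_ids = [f"{population}_{i:04d}" for i in range(samples)]
    matrix = GenotypeMatrix(snp_map, sample_ids, np.vstack(loci_calls))
    panel = PopulationPanel({s: population for s in sample_ids})
    return matrix, panel
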