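from __future__ import annotations

import numpy as np
import pytest

from sweepscan.genotype_model import GenotypeMatrix, PopulationPanel, SnpMap


def build_matrix(
    calls: np.ndarray,
    chroms: list[str] | None = None,
    pos: list[int] | None = None,
    populations: dict[str, int] | None = None,
) -> tuple[GenotypeMatrix, PopulationPanel]:
    """Small deterministic matrix; samples split into populations by count."""
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_samples = calls.shape
    chroms = chroms or ["1"] * n_loci
    pos = pos or list(range(10_000, 10_000 * (n_loci + 1), 10_000))
    smap = SnpMap.from_arrays(
        [f"s{i}" for i in range(n_loci)], chroms, pos,
        ["A"] * n_loci, ["G"] * n_loci,
    )
    populations = populations or {"P1": n_samples}
    samples, assignment = [], {}
    i = 0
    for label, count in populations.items():
        for _ in range(count):
            name = f"{label}_{i}"
            samples.append(name)
            assignment[name] = label
            i += 1
    return GenotypeMatrix(smap, samples, calls), PopulationPanel(assignment)


def random_panel(
    rng: np.random.Generator,
    n_loci: int = 120,
    n_samples: int = 12,
    n_chroms: int = 3,
    missing_rate: float = 0.1,
    mono_fraction: float = 0.45,
) -> tuple[GenotypeMatrix, PopulationPanel]:
    """Random matrix with a high monomorphic fraction (runs arise by chance)."""
    per = n_loci // n_chroms
    chroms, pos = [], []
    for c in range(n_chroms):
        n_c = per + (n_loci % n_chroms if c == n_chroms - 1 else 0)
        chroms.extend([str(c + 1)] * n_c)
        p = np.cumsum(rng.integers(5_000, 80_000, n_c))
        pos.extend(int(x) for x in p)
    f = rng.uniform(0.0, 1.0, n_loci)
    mono = rng.random(n_loci) < mono_fraction
    f[mono] = rng.integers(0, 2, mono.sum())
    calls = rng.binomial(2, f[:, None], size=(n_loci, n_samples)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = -1
    smap = SnpMap.from_arrays(
        [f"r{i}" for i in range(n_loci)], chroms, pos,
        ["A"] * n_loci, ["G"] * n_loci,
    )
    samples = [f"x{j}" for j in range(n_samples)]
    matrix = GenotypeMatrix(smap, samples, calls)
    panel = PopulationPanel({s: "Pop" for s in samples})
    return matrix, panel


@pytest.fixture
def tiny_matrix() -> tuple[GenotypeMatrix, PopulationPanel]:
    # 6 loci x 5 samples, one chromosome; locus 3 has a missing call
    calls = np.array(
        [
            [0, 0, 1, 0, 0],
            [0, 0, 0, 0, 0],
            [2, 2, 2, 2, 2],
            [0, -1, 0, 0, 0],
            [1, 2, 1, 0, 2],
            [-1, -1, -1, -1, -1],
        ],
        dtype=np.int8,
    )
    return build_matrix(calls)
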