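"""Bundled reference catalogues of bovine selective-sweep regions.

These small TSV tables transcribe the published coordinate catalogues of a
genome-wide survey of completed selective sweeps in cattle: sweeps called per
breed on the BovineSNP50 assay (~53K SNPs, 14 breeds), sweeps called on an
ultra-high-density Affymetrix prescreening assay (~2.6M SNPs, 5 breeds), and
the subset of 50K discoveries confirmed by the high-density panel.  All
coordinates are UMD3.1 base pairs; the ``size`` column keeps the published
``end - start`` convention.

They serve as regression fixtures for the interval arithmetic (sizes, means,
grouping, core intersection, cross-assay validation); the underlying
genotypes are not redistributable, so no genotype-level data ships here.

Notes on the transcription:

* one 50K row (Braunvieh, BTA16) prints a size and SNP count inconsistent
  with its own coordinates; it is transcribed as printed and flagged with
  ``size_consistent = 0``;
* the ``block`` column records the published block layout grouping
  overlapping calls of one sweep across breeds; in one high-density block
  (BTA17) the grouped intervals do not all mutually overlap, so the block
  structure is data, not something recomputable from coordinates alone.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import pandas as pd

from .sweep_scan import SweepRegion


def _read(name: str) -> pd.DataFrame:
    with resources.files("sweepscan.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_snp50_sweeps() -> pd.DataFrame:
    """50K-assay sweep catalogue: 32 rows forming 28 region blocks.

    Columns: breeds (comma-joined), chrom, start, end, n_snp, size, block,
    size_consistent.
    """
    return _read("bovine_snp50_sweeps.tsv")


def load_hd_breed_specific_sweeps() -> pd.DataFrame:
    """High-density breed-specific sweeps (65 rows, one region each)."""
    return _read("bovine_hd_sweeps_breed_specific.tsv")


def load_hd_shared_sweeps() -> pd.DataFrame:
    """High-density sweeps shared by >= 2 breeds: 43 rows in 20 blocks."""
    return _read("bovine_hd_sweeps_shared.tsv")


def load_validated_sweeps() -> pd.DataFrame:
    """50K discoveries confirmed by the high-density assay (5 blocks)."""
    return _read("bovine_snp50_validated.tsv")


def load_breed_summary() -> pd.DataFrame:
    """Per-breed panel summary: run length N, monomorphic SNP count, sizes."""
    return _read("bovine_breed_summary.tsv")


def catalogue_regions(
    df: pd.DataFrame, breed_column: Optional[str] = None
) -> list[SweepRegion]:
    """Expand a catalogue frame into per-population :class:`SweepRegion`s.

    Multi-breed rows (comma-joined labels) become one region per breed with
    identical coordinates.  SNP counts are taken from ``n_total``/``n_fixed``/
    ``n_variable`` when present, else from ``n_snp`` (all counted as fixed),
    else from ``n_fixed + n_variable``.
    """
    if breed_column is None:
        breed_column = "breeds" if "breeds" in df.columns else "breed"
    regions: list[SweepRegion] = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        if "n_total" in rec:
            n_total, n_fixed = int(rec["n_total"]), int(rec["n_fixed"])
            n_var = int(rec["n_variable"])
        elif "n_snp" in rec:
            n_total, n_fixed, n_var = int(rec["n_snp"]), int(rec["n_snp"]), 0
        else:
            n_fixed, n_var = int(rec["n_fixed"]), int(rec["n_variable"])
            n_total = n_fixed + n_var
        for breed in str(rec[breed_column]).split(","):
            regions.append(
                SweepRegion(
                    population=breed.strip(),
                    chrom=str(rec["chrom"]),
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    n_total=n_total,
                    n_fixed=n_fixed,
                    n_variable=n_var,
                )
            )
    return regions
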