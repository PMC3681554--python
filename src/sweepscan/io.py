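"""Readers and writers for the standard formats the pipeline touches.

Genotypes come in as VCF (biallelic SNVs, GT field; parsed with cyvcf2) or as
PLINK-style PED/MAP text; the population assignment is a two-column TSV
(sample, population).  Filtered matrices round-trip to VCF; regions go out as
TSV (the tables' closed 1-based convention, size = end - start) and as BED3+
(0-based half-open).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genotype_model import (
    MISSING,
    GenotypeMatrix,
    PopulationPanel,
    SnpMap,
    chrom_sort_key,
)
from .sweep_scan import SweepRegion, regions_to_bed, regions_to_frame

PathLike = Union[str, Path]

_GT_TO_CODE = {0: 0, 1: 1, 3: 2, 2: MISSING}  # cyvcf2 gt_types -> internal codes


def read_vcf(path: PathLike, multiallelic: str = "skip") -> GenotypeMatrix:
    """Load a VCF of biallelic SNVs into a genotype matrix.

    ``multiallelic`` controls records with more than one ALT allele:
    ``"skip"`` drops them with a warning, ``"error"`` raises.  (Splitting is
    not offered because split records would collide on (chrom, pos), which
    the marker map forbids.)  Records are sorted by (chromosome, position)
    with natural chromosome order.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("skip", "error"):
        raise ValueError("multiallelic must be 'skip' or 'error'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[tuple[str, int, str, str, str, np.ndarray]] = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            if multiallelic == "error":
                raise ValueError(
                    f"multi-allelic record at {v.CHROM}:{v.POS} "
                    "(re-run with multiallelic='skip' to drop such records)"
                )
            n_skipped += 1
            continue
        codes = np.array([_GT_TO_CODE[g] for g in v.gt_types], dtype=np.int8)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        records.append((str(v.CHROM), int(v.POS), vid, v.REF, v.ALT[0], codes))
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multi-allelic record(s)", stacklevel=2)
    records.sort(key=lambda r: (chrom_sort_key(r[0]), r[1]))
    snp_map = SnpMap.from_arrays(
        [r[2] for r in records],
        [r[0] for r in records],
        [r[1] for r in records],
        [r[3] for r in records],
        [r[4] for r in records],
    )
    calls = (
        np.vstack([r[5] for r in records])
        if records
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(snp_map, samples, calls)


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: PathLike) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT-only genotypes."""
    smap = matrix.snp_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for chrom in smap.chromosomes:
            sl = smap.chrom_slice(chrom)
            length = int(smap.pos[sl][-1]) if sl.stop > sl.start else 0
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_loci):
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in matrix.calls[i])
            fh.write(
                f"{smap.chroms[i]}\t{smap.pos[i]}\t{smap.ids[i]}\t"
                f"{smap.ref[i]}\t{smap.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_ped_map(ped_path: PathLike, map_path: PathLike) -> GenotypeMatrix:
    """Load PLINK-style text PED + MAP files.

    MAP columns: chrom, id, genetic distance, bp position.  PED columns: six
    metadata fields then two allele calls per locus ('0' = missing).  The
    reference allele of each locus is the alphabetically smaller observed
    allele (PED carries no ref/alt designation); monomorphic loci take the
    observed allele as reference and 'N' as a placeholder alternate.
    """
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"], dtype={"chrom": str},
    )
    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    n_loci = len(map_df)
    if ped.shape[1] != 6 + 2 * n_loci:
        raise ValueError(
            f"PED has {ped.shape[1]} columns; expected {6 + 2 * n_loci} "
            f"for {n_loci} MAP loci"
        )
    samples = ped.iloc[:, 1].tolist()
    a1 = ped.iloc[:, 6::2].to_numpy(dtype=object).T  # (loci, samples)
    a2 = ped.iloc[:, 7::2].to_numpy(dtype=object).T

    order = sorted(
        range(n_loci),
        key=lambda i: (chrom_sort_key(str(map_df.chrom[i])), int(map_df.pos[i])),
    )
    ids, chroms, pos, refs, alts = [], [], [], [], []
    calls = np.empty((n_loci, len(samples)), dtype=np.int8)
    for out_i, i in enumerate(order):
        obs = sorted({a for a in np.concatenate([a1[i], a2[i]]) if a != "0"})
        if len(obs) > 2:
            raise ValueError(f"locus {map_df.id[i]} has >2 alleles: {obs}")
        ref = obs[0] if obs else "A"
        alt = obs[1] if len(obs) > 1 else "N"
        missing = (a1[i] == "0") | (a2[i] == "0")
        alt_count = (a1[i] == alt).astype(np.int8) + (a2[i] == alt).astype(np.int8)
        calls[out_i] = np.where(missing, np.int8(MISSING), alt_count)
        ids.append(str(map_df.id[i]))
        chroms.append(str(map_df.chrom[i]))
        pos.append(int(map_df.pos[i]))
        refs.append(ref)
        alts.append(alt)
    snp_map = SnpMap.from_arrays(ids, chroms, pos, refs, alts)
    return GenotypeMatrix(snp_map, samples, calls)


def write_ped_map(
    matrix: GenotypeMatrix,
    ped_path: PathLike,
    map_path: PathLike,
    panel: Optional[PopulationPanel] = None,
) -> None:
    """Write PLINK-style text PED + MAP (family id = population if given)."""
    smap = matrix.snp_map
    with open(map_path, "w") as fh:
        for i in range(matrix.n_loci):
            fh.write(f"{smap.chroms[i]}\t{smap.ids[i]}\t0\t{smap.pos[i]}\n")
    allele_pairs = {
        0: lambda r, a: (r, r),
        1: lambda r, a: (r, a),
        2: lambda r, a: (a, a),
        MISSING: lambda r, a: ("0", "0"),
    }
    with open(ped_path, "w") as fh:
        for j, sample in enumerate(matrix.samples):
            fam = panel.assignment.get(sample, "FAM") if panel else "FAM"
            fields = [fam, sample, "0", "0", "0", "-9"]
            for i in range(matrix.n_loci):
                a, b = allele_pairs[int(matrix.calls[i, j])](
                    str(smap.ref[i]), str(smap.alt[i])
                )
                fields.extend([a, b])
            fh.write(" ".join(fields) + "\n")


def read_population_tsv(path: PathLike) -> PopulationPanel:
    """Two-column TSV (sample, population), with or without a header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("population file needs two tab-separated columns")
    if str(df.iat[0, 0]).lower() in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    return PopulationPanel(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_population_tsv(panel: PopulationPanel, path: PathLike) -> None:
    pd.DataFrame(
        {"sample": list(panel.assignment), "population": list(panel.assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def write_regions_tsv(regions: Sequence[SweepRegion], path: PathLike) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Sequence[SweepRegion], path: PathLike) -> None:
    regions_to_bed(regions).to_csv(path, sep="\t", index=False, header=False)


def read_regions_tsv(path: PathLike) -> list[SweepRegion]:
    """Read a region TSV written by :func:`write_regions_tsv` (or equivalent)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"population", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        n_total = int(rec.get("n_total", 2))
        n_var = int(rec.get("n_variable", 0))
        n_fixed = int(rec.get("n_fixed", n_total - n_var))
        out.append(
            SweepRegion(
                population=str(rec["population"]),
                chrom=str(rec["chrom"]),
                start=int(rec["start"]),
                end=int(rec["end"]),
                n_total=n_total,
                n_fixed=n_fixed,
                n_variable=n_var,
            )
        )
    return out
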