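# sweepscan

Detection of **completed selective sweeps** in diploid SNP-array genotypes.

Strong selection drives a haplotype to fixation and, through hitch-hiking,
eliminates variation at the markers flanking the selected variant.  On a
genotyping array a completed sweep therefore appears as a run of
map-adjacent SNPs with (near-)zero minor allele frequency within a
population.  `sweepscan` is for population geneticists and breeding
researchers who want to scan array panels — cattle-style 50K panels or
ultra-high-density prescreening panels — for such runs, control the false
discovery rate analytically, and cross-validate calls between populations
and assays.

## What it computes

**Scans.** Per population, on the filtered marker map:

* *low density* (~37 kb spacing): maximal runs of ≥ N contiguous SNPs
  spanning ≥ 200 kb with every MAF ≤ 0.01 (the allowance absorbs ~0.5%
  genotyping error and new mutation);
* *high density* (~1 kb spacing, small samples): ≥ 20 contiguous SNPs over
  ≥ 100 kb where at most 5% of loci are *variable* — MAF > (2M)⁻¹ with M the
  number of genotyped individuals at the locus, i.e. more than one
  heterozygote — and no more than 3 variable loci are consecutive.

**Error model.** Assuming independent loci, with per-SNP monomorphic
probability *q*, *S* SNPs and *C* chromosomes, the expected number of chance
windows of *N* contiguous monomorphic SNPs is

```
E[FP](N) = q^N · (S − C·(N − 1))
```

and two single false-positive N-SNP runs in different populations coincide
anywhere in the genome with probability (2N − 1)/(S − C·(N − 1)).  Raising N
suppresses false positives geometrically but raises the smallest detectable
sweep to ≈ (N − 1) median marker intervals — the trade-off behind
population-specific run lengths on ascertainment-biased arrays.

**Comparison.** Overlapping calls from different populations are grouped by
single linkage; each group's *core region* is the intersection of member
intervals, and *core haplotypes* (the fixed allele at each core locus) are
compared across populations by Hamming distance.  Discovery regions are
*validated* by ≥ 1 bp overlap with an independent (e.g. higher-density)
region set, in any population by default.

**Plus**: gene-overlap annotation from GFF3/BED, a synthetic-panel generator
with planted sweeps for testing and calibration, bundled published bovine
sweep catalogues (UMD3.1 coordinates) used as regression fixtures, and a CLI
(`simulate` / `filter` / `scan` / `fpr` / `compare` / `validate` /
`annotate` / `run`).

## Worked example

```python
from sweepscan import (
    PopulationSpec, PlantedSweep, snp50_config, simulate_panel,
    LowDensityScanParams, scan_low_density, low_maf_fraction,
    ScanErrorModel, expected_false_positive_regions, recommend_run_length,
)

cfg = snp50_config(
    [PopulationSpec("Angus", 40, low_maf_fraction=0.16),
     PopulationSpec("Brahman", 40, low_maf_fraction=0.25)],
    seed=42, n_snps=5_000,
    planted_sweeps=(PlantedSweep({"Angus"}, "1", 1_700_000, 2_100_000),),
)
res = simulate_panel(cfg)
for pop in ("Angus", "Brahman"):
    q = low_maf_fraction(res.matrix, res.panel, pop).n_monomorphic / res.matrix.n_loci
    model = ScanErrorModel(q=q, S=res.matrix.n_loci, C=29)
    n = recommend_run_length(model, max_expected_fp=0.1)
    regions = scan_low_density(res.matrix, res.panel, pop, LowDensityScanParams(n_min=n))
    print(f"{pop}: monomorphic fraction {q:.3f}, N={n}, "
          f"E[FP]={expected_false_positive_regions(model, n):.3f}, "
          f"{len(regions)} region(s)")
    for r in regions:
        print(f"  BTA{r.chrom}:{r.start:,}-{r.end:,}  {r.n_total} SNPs  size {r.size:,} bp")
```

prints

```
Angus: monomorphic fraction 0.156, N=6, E[FP]=0.070, 1 region(s)
  BTA1:1,710,188-1,935,576  6 SNPs  size 225,388 bp
Brahman: monomorphic fraction 0.220, N=8, E[FP]=0.026, 0 region(s)
```

The Angus panel carries a planted sweep at BTA1:1.70–2.10 Mb and the scan
recovers it as the run of its markers (region boundaries sit on the first
and last swept SNPs, so they lie inside the planted interval).  The run
length N is chosen per population from its monomorphic fraction — the
more ascertainment-biased Brahman panel (22% monomorphic) needs N = 8 to
hold the expected chance-run count below 0.1, and its null panel yields no
calls.  The `size` column follows the end − start convention of the
published tables this package reproduces.

The same pipeline from the shell:

```sh
sweepscan simulate --preset 50k-like --n-snps 5000 \
    --population Angus:40:0.16 --sweep 1:1700000-2100000:Angus \
    --seed 42 --out-prefix panel
sweepscan scan --vcf panel.vcf --populations panel.populations.tsv \
    --n-min 6 --out-tsv regions.tsv --out-bed regions.bed
sweepscan fpr --q 0.15 --n-snps 52942 --n-min 5 --n-max 8
```

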