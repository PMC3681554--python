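# Methods

## The signal and the detection model

A completed selective sweep fixes one haplotype in a population, removing
variation at every marker it spans.  On a genotyping array this appears as a
run of map-adjacent SNPs that are monomorphic (or nearly so) within the
population.  `sweepscan` detects such runs per population on the retained,
filtered marker map; "contiguous" always means adjacent in map order after
filtering, so every scan is conditional on the filters applied before it.

Two rule sets correspond to two assay densities:

**Low density** (50K-like, median inter-marker gap ~37 kb).  A sweep is a
maximal run of at least `n_min` adjacent loci spanning at least `span_min` bp
(defaults 5 and 200 kb) in which every locus has MAF ≤ `maf_max` (default
0.01).  The non-zero MAF allowance absorbs genotyping error (~0.5% per call
on these assays), new mutation on an old swept haplotype, and mis-assembled
markers; run loci with 0 < MAF ≤ `maf_max` are reported in `n_variable` and
masked with a sentinel in the fixed-haplotype vector.

**High density** (HD-like, median gap ~1 kb, small samples).  With M called
individuals at a locus, the locus is *variable* iff MAF > 1/(2M) — i.e. more
than one heterozygote, so a single erroneous call cannot break a sweep.  A
region must have ≥ `n_min` loci (default 20) spanning ≥ `span_min` (default
100 kb), with ≤ `variable_fraction_max` (default 5%) variable loci and no
more than `max_contiguous_variable` (default 3) consecutive variable loci;
region boundaries are always fixed loci.

Region size is reported as `end − start` of the first and last run loci (the
convention of the published coordinate tables this package regression-tests
against), which differs by 1 from the BED interval length; the BED writer
keeps 0-based half-open coordinates and the TSV writer keeps the table
convention.

### Delimiting high-density regions

The four constraints do not uniquely delimit regions when the 5% fraction
binds, so delimitation is a declared policy: chromosomes are first cut at
unclassifiable loci and at variable runs longer than
`max_contiguous_variable` (no admissible region can cross either); boundary
variable loci of each remaining segment are trimmed; then a left-to-right
greedy pass anchors at the first unconsumed fixed locus and takes the
*longest* candidate right end — candidates are the last fixed locus before
each variable run, plus the segment end — whose whole-interval variable
fraction passes.  If the winning interval also meets the count and span
thresholds it is emitted and scanning resumes after it; otherwise the anchor
advances past the next variable run, so admissible intervals that begin
after a variable-dense prefix are still found.  The policy is deterministic,
linear-time in practice, emits pairwise-disjoint regions, and — unlike a
prefix-fraction greedy — tolerates a variable locus early inside a long
sweep (e.g. a 248-locus region whose 7th locus is variable: the prefix
fraction 1/7 would fail, the whole-interval fraction 1/248 passes).
Maximality is policy-relative; the test suite checks independently that no
reported region can be extended to the adjacent fixed locus on either side
without breaking a rule.

An optional `max_gap` (both scanners, default off) additionally breaks runs
at large inter-marker gaps; the published scans used none.

Loci with no called genotype in a population have undefined MAF and break
runs — a conservative choice that can only split, never create, a region.

## Allele frequencies and filters

MAF is computed from called alleles only, in numerator and denominator,
folded to [0, 0.5]; it is invariant to ref/alt relabelling, and a locus with
all calls missing raises a distinct no-data signal rather than returning 0.
Filters are projections (idempotent, genotype-preserving): overall and
per-population call-rate thresholds (defaults 0.85 and, for multi-population
HD panels, 0.50 within each population) and chromosome exclusion (X by
default: hemizygous in all-male panels and assembly-fragile).  Whether X
removal precedes the call-rate filter is configurable (default: X first);
the two orders differ only if X loci would change nothing else, so the
default is the cheaper one.

## The analytic false-positive model

If a fraction `q` of SNPs is monomorphic and loci are independent, an
`N`-SNP window is all-monomorphic with probability `q^N`; with `S` SNPs on
`C` chromosomes there are `S − C(N−1)` window placements, hence

    E[FP](N) = q^N · (S − C(N−1))

expected chance windows per population.  Under the study conditions
(q = 0.15, S = 52,942, C = 29) this is 4.0 at N = 5 and 0.6 at N = 6; at
HD density (S = 2,575,339, N = 20) it is below 10⁻¹⁰.  The formula counts
*windows*: a maximal qualifying run of length L ≥ N contains L − N + 1 of
them, so the empirical cross-check in the test suite counts windows (derived
from scanner output as Σ(L − N + 1)), not maximal runs — the two differ by a
factor ≈ (1 − q)² that would otherwise be misread as a calibration error.
Chromosome-end effects are ignored exactly as the closed form ignores them.

The two-population coincidence probability uses the same position count:
with `P = S − C(N−1)` placements and an overlap window of `w = 2N − 1`
positions, two single false positives overlap somewhere with probability
`P · (1/P · w/P) = w/P` ≈ 0.0002 for N = 6 — which is why a sweep found in
two or more populations is effectively self-validating.

`recommend_run_length` returns the smallest N ≥ 5 with E[FP] below a budget.
It is advisory: the published per-breed run lengths (5–10) do not follow any
stated closed form applied to the per-breed monomorphic fractions (e.g. the
most ascertainment-biased breed would still show an expectation ≫ 1 at its
assigned N), so N remains an explicit, population-level parameter.  Larger N
also raises the smallest detectable sweep to about `(N−1)` median marker
intervals (185 kb at N = 6 on a 37 kb map) — the trade-off the helper
operationalises but does not decide.

Independence across loci is assumed throughout; linkage disequilibrium makes
real monomorphic runs longer than independent ones, so the analytic
expectation is an approximation on real data, exact only under the
LD-free simulator below.

## Cross-population comparison and validation

Overlapping regions from different populations are clustered by single
linkage (≥ 1 bp overlap, same chromosome); a group's *core* is the
intersection of its members (max start, min end).  Chained groups without a
common intersection are kept whole and flagged rather than split, preserving
single-linkage semantics while exposing the ambiguity.  Core haplotypes —
the major allele at each fixed core locus — are compared between two
populations by Hamming distance at shared core loci, matching loci by
(chromosome, position) so that assays with different marker names remain
comparable; sentinel (variable) positions are skipped and counted
separately.  A discovery region is validated when ≥ 1 region from an
independent scan overlaps it by ≥ 1 bp, in any population by default:
cross-population confirmation is intentional, as phylogenetically close
populations can carry the same swept haplotype.  A reciprocal-overlap
fraction is deliberately not required (plain overlap matches the published
validation logic); callers needing same-population confirmation set a flag.

## The synthetic-data generator

`simulate.simulate_panel` emulates exactly the features the scans are
sensitive to, and nothing more:

* **Map**: per-chromosome positions from exponential gaps whose median is
  the target inter-marker interval (37 kb for the 50K profile, 975 bp for
  the HD profile; 29 autosomes; profile defaults keep the published panel
  sizes of 52,942 and 2,575,339 retained SNPs).
* **Spectrum**: per population and locus, a monomorphic point mass
  (`low_maf_fraction`, default 0.15 — the ascertainment-bias knob; the
  published per-breed monomorphic fractions run ~12–25%) plus a folded-Beta
  segregating MAF on (0, 0.5] (default uniform).  Genotypes are binomial
  draws per diploid sample.
* **Planted sweeps**: all listed populations receive one shared fixed
  haplotype across the interval, with an optional per-locus residual
  heterozygote (`residual_variation_rate`) standing in for new mutation.
* **Noise**: symmetric genotyping error (a miscalled genotype becomes one of
  the other two states uniformly; default rate 0.005) and missingness
  (default 0.02), applied last.

Output is a pure function of the configuration including the seed.

Because a segregating locus can still be drawn monomorphic in a finite
sample (probability `m^2M + (1−m)^2M`), the realized monomorphic fraction
exceeds the point mass.  `calibrate_low_maf_fraction` solves the point mass
so the *realized* per-locus monomorphic probability equals a target — the
calibration used to put the null simulation exactly at q = 0.15 before
comparing against the analytic expectation.

What the generator does **not** model: linkage disequilibrium, drift,
demography, recombination, genotype-calling artefacts correlated across
loci, or sex chromosomes.  Passing tests therefore demonstrate algorithmic
correctness and calibration under the stated independence assumptions, not
performance on LD-structured real genotypes.

`make_table_fixture` deterministically reconstructs a published table row
(coordinates, SNP counts, variable-SNP counts) as a scannable panel:
evenly spaced loci with the first/last at the printed bounds, isolated
interior variable loci (two heterozygotes each make a locus variable under
the 1/(2M) rule; one sits exactly at the threshold), high-MAF flanks.  Rows
whose geometry cannot be realised are rejected.

## Numerical and interface choices

* Genotypes are `int8` codes {0, 1, 2, −1(missing)}; biallelic only.
  Multi-allelic VCF records are skipped with a warning (or rejected):
  splitting them would collide on (chrom, pos), which the map forbids.
* Chromosome labels are strings in natural sort order; the autosome count is
  a parameter, never hard-coded.
* PED/MAP input assigns the alphabetically smaller observed allele as
  reference (PED carries no designation); genotype content is preserved up
  to that relabelling, under which MAF is invariant.
* At a fixed locus the major allele is the alternate iff its frequency
  exceeds 0.5; the only possible tie (M = 1, one heterozygote) resolves to
  the reference.
* Regions separated by a single disqualifying locus are never merged; the
  scans report runs, not merged clusters.
* Test problem sizes: the oracle-equivalence suite runs 500 seeded panels of
  ≤ 200 loci against an exhaustive interval enumerator; the null-model
  calibration uses 200 replicates of the full 52,942-SNP × 29-autosome map
  with 40 diploid samples; HD-profile examples instantiate smaller panels
  explicitly while the profile defaults keep the published sizes.

## Known limitations

* No LD-aware error theory; the analytic model and simulator share the
  independence assumption (documented above).
* The scanners detect *completed* sweeps only; ongoing sweeps, soft sweeps
  and statistics such as iHS/F_ST/EHH are out of scope.
* The bundled reference catalogues are coordinate tables, not genotypes;
  genotype-level reproduction of the published calls is not possible from
  public data, and one catalogue row carries a printed size inconsistent
  with its own coordinates (transcribed as printed, flagged
  `size_consistent = 0`).
* Gene annotation is interval plumbing only (GFF3/BED in, overlap table
  out); functional enrichment is out of scope.
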