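# Methods

`rohdel` implements the genotype-level analysis of deleterious variation
in small managed populations: per-individual heterozygosity tracks, run
of homozygosity (ROH) detection, ancestral/derived polarization, and
four burden statistics. This note records the models, the parameters
that matter, and the design choices made where more than one reasonable
convention exists.

## Windowed coverage-corrected heterozygosity

The genome is tiled into non-overlapping bins (`bin_size`, default
10 kb). A heterozygous call contributes to a bin only if its read depth
lies in the trusted window `[min_depth, max_depth_factor x mean_cov]`
(defaults: 4 reads absolute minimum, 2x the sample's genome-wide mean
coverage as maximum; both boundaries inclusive). The two cut-offs
remove low-confidence calls and likely collapsed repeats respectively.
The absolute/relative reading of the pair is forced: a minimum at 4x
the mean would exceed the 2x-mean maximum.

The raw count is corrected for sites lost to coverage:

    het_corrected = n_het x bin_size / n_wellcovered

which is exact when well-covered sites are missing at random within the
bin. `n_wellcovered` counts all sites (variant and invariant) with
passing depth; since a VCF carries variants only, the caller may supply
a per-bin callable-sites track (a per-base depth summary reduced to
bins; the simulator emits one directly). Without a track the count is
estimated as the bin's depth-pass fraction at variant sites times the
bin span — adequate when variant density is even, biased in bins with
few variants, hence the track is preferred. Bins with fewer than
`min_wellcovered_sites` (default 1,000) well-covered sites, and partial
terminal bins, are flagged unusable and excluded from the genome mean;
partial-bin exclusion avoids span-dependent bias in the mean.

The reference diversity for ROH calling is each individual's own
genome-wide mean of `het_corrected` over usable bins, not a cohort
mean: inbreeding depresses an individual's background diversity and the
thresholds should scale with it.

## ROH detection

A candidate ROH is seeded wherever a sliding window of `scan_bins`
consecutive bins (default 10, i.e. 100 kb) has mean heterozygosity
below `candidate_factor` (default 0.25) of the genome mean; windows
slide by one bin and overlapping qualifying windows are unioned.
Sliding (rather than jumping) windows are required for the short
(<100 kb) class to have sensible edge behaviour.

Local assembly or alignment errors are tolerated through relaxation: a
bin inside a candidate may carry up to `bin_relax_factor` (2x) the
genome mean, provided the candidate's overall mean stays at or below
`roh_ceiling_factor` (1/3) of the genome mean. In practice single noisy
bins are absorbed at the seeding stage (a 100-kb window containing one
<= 2x-mean bin among low bins still qualifies); bins above the
relaxation limit always break a candidate, and a candidate whose
overall mean exceeds the ceiling loses the relaxation privilege and is
re-split at every at/above-threshold bin. Candidates may not begin or
end on a relaxed or unusable bin — without that rule candidates creep
outward onto ordinary background bins. Explicit merging across a gap is
allowed only when the gap consists entirely of unusable bins (a
coverage hole carries no evidence either way); gaps of usable
above-threshold bins were already judged at seeding and remain breaks.
An earlier variant that also bridged usable gaps merged planted tracts
separated by megabases of ordinary diversity and was rejected on the
simulator's truth.

Unusable bins interior to a candidate count toward its length but not
its covered length; candidates with `covered_length / length` below
`min_covered_fraction` (2/3) are dropped. Detected tracts are
classified by length: short < 100 kb, medium 0.1-3 Mb, long >= 3 Mb
(the >= convention at 3 Mb is adopted and configurable). The
per-individual inbreeding summary is `G_{i,j} = L_ROH / L_genome` per
size class j in {short, medium, long, any}; the class fractions sum to
G(any) exactly because classes partition the tracts.

The detector is validated two ways: exhaustive equality against an
independently written brute-force implementation of the same staged
rules on random tracks of up to 200 bins, and recovery of planted
tracts in simulation (20 individuals, one 50-Mb chromosome, tracts of
roughly 1-8 Mb, background ~20 het/10 kb), where base-level recall and
precision exceed 0.99 and per-individual G(any) error stays under 0.002
— boundary error is essentially one bin per tract edge.

## Polarization and functional classes

The ancestral allele at a bi-allelic SNP is the allele for which every
outgroup sample is homozygous; heterozygous or missing outgroup
genotypes break unanimity and leave the site non-polarizable (flagged
and counted, not silently dropped). Strict unanimity over all outgroups
is the default; two-of-three style rules are not implemented. Working
on the ancestral/derived scale rather than ref/alt removes reference
bias, and the assignment is invariant under a consistent ref/alt swap
(property-tested). Focal genotypes map to homozygous-ancestral /
heterozygous / homozygous-derived / missing.

Coding variants are classified from consequence and SIFT score:
synonymous; nonsynonymous tolerated (SIFT >= 0.05); nonsynonymous
deleterious (SIFT < 0.05); loss of function (stop gain/loss, start
loss, frameshift — regardless of SIFT). Missense records without a
SIFT score are left unclassified and excluded from class counts.
"Damaging" means deleterious or LoF; a high-confidence deleterious tier
additionally requires GERP > 1.0. Confidence filters keep only variants
in 1:1 orthologous genes with RNA-seq expression coverage >= 200 (both
thresholds are config keys; the RNA boundary is inclusive). Indels and
multi-allelic records are skipped with reason counts.

## Burden statistics

**Homozygosity LRT.** For one functional class, individual i carries
x_i homozygous-derived genotypes among n_i non-missing genotypes at
passing, polarizable, segregating sites (fixed-derived sites carry no
between-group contrast and are excluded from the test, though they are
retained in spectra). Each genotype is a Bernoulli draw; under the null
both groups share one proportion p, under the alternative each group
has its own. MLEs are pooled ratios (sum x / sum n), the statistic is
Lambda = -2 (ll_0 - ll_1), and p comes from the chi-square(1) survival
function (equivalently erfc(sqrt(Lambda/2))). Boundary MLEs (0 or 1)
use the 0·log 0 = 0 convention. A per-individual binomial with shared p
differs from the per-genotype Bernoulli only by a combinatorial
constant, so MLEs and Lambda are identical. The choice of denominator
(all non-missing genotypes, not only derived-carrying ones) is the
natural one for a proportion of genotypes and is encapsulated in the
count-table construction. Calibration: under a simulated null (equal
proportions 0.2, 40+40 individuals, 1,000 sites, 1,000 replicates) the
rejection rate at alpha = 0.05 lands inside the exact binomial 99%
interval.

**Genetic load.** Per individual, the ratio of deleterious to
synonymous site counts, separately for heterozygous and
homozygous-derived genotypes, averaged within groups; individuals with
zero synonymous sites in a state are flagged undefined and excluded
from the group mean.

**DAF spectrum.** Derived allele frequency = derived-allele count over
2x the non-missing diploid samples at the site, binned into ten classes
[0, 0.1), ..., [0.9, 1.0] with the last bin closed so fixed derived
sites are retained; all-missing sites are skipped with a log entry.
Bin counts are conserved and invariant to sample order.

**ROH enrichment.** Each homozygous-derived genotype of an individual
is inside or outside each ROH size class (membership by sorted-interval
search, verified against a per-position linear scan on 1e5 random
positions); rows carry counts, the fraction inside, and G_{i,j}. The
headline readout is the Pearson correlation (with its t-transform
p-value) of fraction-in-ROH against G across individuals, expected
positive when homozygous damaging variants concentrate in autozygous
segments.

## The synthetic-data generator

The generator emulates the joint structure the statistics consume, not
sequence evolution. Per group, each individual receives planted IBD
tracts: a Poisson number per chromosome (`roh_rate_per_mb` x length),
log-normal lengths, uniform starts, clipped and merged. Inside a tract
the genotype is homozygous for one haplotype draw from the site
frequency (heterozygous with probability `in_tract_het_leak`, default
0.01, standing in for genotyping error and tract-edge mosaicism);
outside, genotypes are Hardy-Weinberg draws from the site's derived
allele frequency. Frequencies per functional class are Beta draws —
synonymous Beta(0.5, 0.5) (drift-dominated U-shape), tolerated
Beta(0.4, 0.8), deleterious and LoF Beta(0.2, 2.0) (purifying-selection
skew toward rare). Site positions are uniform; an optional per-class
bias places a configurable fraction of a class inside the planted-tract
union, modelling the concentration of damaging homozygotes in
autozygous regions. The ancestral allele is REF with probability 0.5 so
reference-bias handling is exercised; outgroups are homozygous
ancestral up to `outgroup_error_rate`. Depth is Poisson around the
per-sample mean (13.4x default, a realistic mid-coverage design);
missingness is uniform at 2%. The per-bin well-covered track is drawn
Binomial(bin span, P(depth filter passes)) under the same Poisson
depth model. Default cohort: two groups of 10 on a 20-Mb chromosome,
with the recently bottlenecked group carrying fewer-but-longer tracts
at a higher rate, and ~8,200 coding sites in the published class
proportions (synonymous : tolerated : deleterious : LoF roughly
75 : 21 : 5 : 1).

What the generator does **not** emulate: linkage disequilibrium,
recombination, selection dynamics, shared tracts between relatives,
non-uniform variant density, mapping artefacts, or genotype-likelihood
uncertainty. Passing tests therefore demonstrate correctness of the
statistics and detection rules under the stated sampling model, not
robustness to alignment or calling artefacts in real data.

## Problem sizes and numerical choices

Test and acceptance runs use one 50-Mb chromosome with 400,000 sites
for ROH recovery (background ~20 het/10 kb, matching the corrected
heterozygosity a mid-coverage genome scan yields), 1,000 null
replicates for LRT calibration, 1e5 random positions for the
enrichment oracle, and 1e4 Beta draws per class for spectrum checks —
sizes at which Monte-Carlo error is far below the assertion margins.
The grid-search check of the LRT MLEs uses a 1e-6-step grid, so
agreement is asserted at 1.1e-6 to cover the grid's own quantization.
Randomness is always through an explicitly seeded NumPy generator;
identical configuration gives bit-identical outputs, including file
serializations.

## Known limitations

- The published per-individual genotype counts are not available, so
  the LRT reproduces the published chi-square conversions and its own
  calibration, not the published Lambda values themselves.
- The correction formula assumes missing well-covered sites are
  missing at random within a bin.
- Heterozygosity windows and ROHs are autosome-oriented; sex
  chromosomes need ploidy-aware handling that is out of scope.
- The estimated (trackless) well-covered count degrades in bins with
  few variant sites; supply a depth-summary track for real data.
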