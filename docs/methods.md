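# Methods

## Statistics on the site frequency spectrum

All diversity estimators are sums of per-site contributions over biallelic
SNPs. For a site with derived count *d* among *n* called alleles:

    pi_site = 2 d (n-d) / (n (n-1))        (unbiased heterozygosity)
    L_site  = d / (n-1)                    (linear derived weighting)
    H_site  = 2 d^2 / (n (n-1))            (quadratic derived weighting)

Summed over a window these give θπ, θL and θH; θW = S/a_n with
a_n = Σ 1/i (i < n). The identity θπ − θH = 2(θπ − θL) holds exactly on
fully polarized data and is enforced by a property test. Monomorphic
sites contribute zero; per-bp values divide by the window's callable
length from the mask, never by the window size.

The neutrality tests are the variance-normalized differences

    D = (θπ − θW)/σ̂,   H = (θπ − θL)/σ̂,   E = (θL − θW)/σ̂,

with the standard normalizations: Tajima's coefficients for D, and for H
and E the variance expressions in θ̂ = S/a_n and the unbiased
θ̂² = S(S−1)/(a_n²+b_n). These formulas are cross-checked in the test
suite against straight-line reimplementations and, for the variance of
θL−θW, against the empirical variance over 20,000 independent msprime
windows (agreement to three significant figures).

**Polarization.** The ancestral allele is the allele carried by the
outgroup when every outgroup sample is non-missing and homozygous for the
same allele; otherwise the site's ancestral state is unknown. Unknown
sites are excluded only from the statistics that need polarization (θL,
θH, H, E); θπ, θW and D are computed from minor/major counts, which are
polarization-invariant. Under infinite sites, outgroup mispolarization is
effectively confined to sites monomorphic within the ingroup, which carry
zero weight in every estimator; the scan therefore loses nothing by the
simple homozygous-outgroup rule.

**Missing data.** Per-site contributions use each site's own called-allele
count n; the variance constants of D/H/E use the window's median n.
Sites with fewer than 4 called alleles in a population are dropped from
that population's statistics.

**Undefined values.** A window with no (polarized) segregating sites has
no defined D (H, E); these are emitted as NA, never as 0, and excluded
from quantile scans for that statistic.

### Known finite-sample behaviour

The variance-normalized tests do not have mean exactly zero at finite θ:
the numerators are unbiased, but they correlate with the S-based variance
estimate in the denominator. At n = 26 sequences and θ = 5 per window the
intrinsic means are ≈ −0.08 (D), +0.07 (H) and −0.12 (E), reproduced
identically by this package's simulator and by msprime. Window-mean E on
neutral data therefore sits measurably below zero; empirical-quantile
outlier calling is unaffected (it ranks windows within the realized
distribution), but E should not be compared against a nominal zero line.

## Windows and genome-wide aggregates

Windows are 1000 bp with 50 bp steps (both configurable), anchored at
coordinate 0 of each chromosome in 0-based half-open coordinates; the
trailing windows truncate at the chromosome end. Windows with fewer than
150 callable bp are removed and counted in the log. Normalized diversity
divides each window's θπ by the population's mean θπ over retained
windows, so its mean is exactly 1 per population.

Genome/genic/nongenic summaries are length-weighted: per-site
contributions are summed over all callable sites of the partition and
divided by the partition's callable length. Means of window values are
available from the window table but are not the headline aggregate, since
they weight short trailing windows equally.

## Differentiation and divergence dating

Hudson-style FST is used throughout: per site, within-population
diversity is the mean of the two unbiased heterozygosities and
between-population diversity is p₁(1−p₂)+p₂(1−p₁); the weighted estimate
is the ratio of summed numerators to summed denominators
(ratio-of-averages). Negative per-site numerators are retained. This
estimator is the default because the isolation-model dating formula is
exact for it:

    FST = 1 − π_w/d_xy   ⇒   d_a = π_w FST/(1−FST) = d_xy − π_w = 2 μ T.

π̄_w is the unweighted mean of the two populations' genome-wide per-bp θπ.
Defaults μ = 10⁻⁸ per bp per generation and a 10-year generation time.
The dating assumes current within-species diversity proxies ancestral
diversity; when the split is recent relative to 2N generations the method
inherits that assumption's bias, which the simulator makes explicit (see
below). A haploid-allele Weir–Cockerham estimator is available for
comparison (`weir_cockerham_site`).

PCA mean-centers each site (missing genotypes mean-imputed) and
eigendecomposes the sample covariance via SVD; component signs are
arbitrary.

## Inbreeding and mating system

Per individual, F maximizes the likelihood of its genotype calls under

    P(hom ref) = (1−p)² + Fpq,  P(het) = 2pq(1−F),  P(hom alt) = p² + Fpq,

over F ∈ [0,1] by bounded 1-D optimization, with allele frequencies taken
from the remaining samples of the individual's population (leave-one-out,
avoiding self-reference). Heterozygote excess truncates at F = 0.
Equilibrium partial selfing maps s ↔ F by F = s/(2−s).

Limitations: treating finite-panel frequencies as known inflates F̂ by
roughly the reciprocal of the panel's allele count (about +0.05 with 12
diploids, +0.02 with 30, measured on simulations with known F); with the
13-per-species design the population means carry a small positive offset.
The estimator also cannot distinguish selfing from biparental inbreeding.

## Candidate scan

Gene values default to the mean of the statistic over retained windows
overlapping the gene span (min is available, as sweeps are local minima);
genes with no retained window are excluded from the scored universe.
Candidates are genes at or beyond the empirical 5% quantile, ties
included. Candidate regions are maximal runs of consecutive retained
windows beyond the threshold spanning ≥ 50 kb; runs bridge
callability-dropped windows but break at any retained window inside the
threshold.

The overlap of two candidate sets is tested by redrawing |A| genes
uniformly without replacement from the universe (default 1000
permutations) with the add-one p-value (1+#{perm ≥ obs})/(1+n_perm), so
the smallest reportable value at 1000 permutations is ≈ 0.001;
the exact hypergeometric expectation and tail are reported alongside.
Discreteness makes these p-values conservative (valid), which the tests
assert; they are not exactly uniform under the null.

## The synthetic-data generator

The generator is an exact Kingman coalescent with infinite sites and no
intra-window recombination: 1 kb segments along a chromosome are
independent coalescent replicates. This matches the window-marginal
statistics the pipeline computes; it does not emulate linkage
disequilibrium between nearby windows, read-depth or genotyping error
(genotypes are exact by design), so passing tests demonstrate estimator
correctness under the model, not robustness to call errors.

Structure is divergence-in-isolation: lineages coalesce only within their
population (rate 1/(2N_k) per pair per generation) until the split time
T, then in an ancestral population of size N_anc; a single outgroup
lineage joins deeper in the past. The true ancestral state is the root
state, written to the VCF's AA field; the reference allele is the first
haplotype of the reference-like (peach) population, so REF/ALT and
ancestral/derived orientations decouple realistically.

**Calibration.** Configured per-population θ values are targets for
*realized* diversity. Expected pairwise coalescence time within a
daughter population is 2N(1−e^(−T/2N)) + e^(−T/2N)·2N_anc, so 4Nμ alone
overshoots when lineages survive past the split; each N is solved from
its θ target by bisection on that expression. N_anc defaults to
mean(θ)/(4μ), which makes ancestral diversity equal the mean target and
the net-divergence dating estimator unbiased (d_a = 2μT in expectation).
With equal θ targets this reduces to N = N_anc, the design used in the
split-time recovery test (T = 50,000 generations, θ = 4×10⁻⁴, 500
windows, recovery within 15%).

**Defaults** encode the study contrast: 13+13 diploids plus one outgroup;
θ targets 0.0186 and 0.0027 per bp (≈7:1); split 800,000 generations
(8 MY at 10 yr/generation), outgroup join 2,400,000 generations; μ =
10⁻⁸; selfing s = 0 (outcrosser) and s = 0.329 (equilibrium F = 0.197);
five 200 kb chromosomes with 2 kb genes every 5 kb; two diversity-
reduction sweeps (factor 0.05) and two SFS-skew sweeps planted.

**Selfing** is modeled as instantaneous identity-by-descent: an
individual's two gene copies are the same haplotype with probability
F = s/(2−s), drawn independently per segment (equilibrium inbreeding at
unlinked loci, not a multi-generation pedigree). Realized per-individual
IBD fractions are recorded in the truth table.

**Planted sweeps.** Reduction mode keeps each within-population
polymorphism with probability equal to the factor and otherwise fixes the
majority allele — the low-θπ, high-FST signature. Skew mode resamples
polymorphic sites toward derived count n−1 ("high": drives Fay & Wu's H
strongly negative and, necessarily, Zeng's E positive, since θL then
exceeds θW) or toward singletons ("low": the post-sweep recovery
signature driving D and E negative).

## Problem sizes used in the checks

Neutral calibration uses 2,000 windows (n = 26, θ = 5); selfing-rate
recovery uses 30 diploids × ~2,800 sites per grid point (the panel size
keeps the leave-one-out frequency bias well inside the ±0.05 band);
split-time recovery uses 500 one-kb windows; planted-sweep recovery scans
a 2 Mb chromosome carrying 400 genes with 10 planted 20-fold-reduction
regions at the 5% quantile. The full default pipeline (1 Mb, 27 samples)
runs in well under a minute on one CPU.
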