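# Methods

## Scope and model

`migradiv` analyses the situation where two recently diverged, hybridizing
bird populations — e.g. the SW-migrating southern and SSE-migrating northern
willow warbler phenotypes around the Baltic — are genetically almost
indistinguishable genome-wide, yet carry a few multi-megabase chromosome
regions in which two deeply diverged haplotype clades segregate without
recombining with each other (the geometry expected of inversion
polymorphisms). The package provides the four analysis layers such a study
needs, plus a generator that produces study-shaped data with known truth.

### Windowed statistics

All estimators work on unphased diploid alt-allele dosages and
non-overlapping 10-kb windows, normalized by the number of *callable* sites
(positions at which a variant could have been detected given the coverage
and missingness filters). Windows with fewer than 5,000 callable sites carry
no statistics; windows with fewer than 25 SNPs carry no F_ST.

* **F_ST** — Weir & Cockerham (1984) variance components a (among
  populations), b (among individuals), c (within individuals); the window
  value is the ratio of sums Σa/Σ(a+b+c). Negative per-site components are
  retained unclamped; sites with a zero denominator are undefined, not zero.
* **π** — Σ 2p̂q̂·n/(n−1) over sites, divided by callable sites; n is the
  per-site count of called alleles, so the estimator is unbiased for the
  population heterozygosity.
* **Tajima's D** — computed from the window totals of pairwise differences
  and segregating sites with the standard 1989 constants; n is the group's
  haplotype count. Undefined at S = 0 and excluded from means.
* **d_XY, d_A** — d_XY = Σ[p̂ₓ(1−p̂ᵧ) + p̂ᵧ(1−p̂ₓ)]/callable and
  d_A = d_XY − (πₓ+πᵧ)/2. The identity holds to machine precision on every
  window by construction. Split time is t = d_A/(2μ_year) over a
  configurable yearly-rate range whose default (1.56–3.33 × 10⁻⁹) spans
  typical passerine nuclear rates.

Per-group diversity statistics are computed on the "pure" subsets — samples
called homozygous for the same clade in *all* divergent regions — while
F_ST contrasts the full phenotype populations. A sample heterozygous or
unassigned in any region is excluded from the pure subsets.

### Haplotype-block genotyping

Within a region, samples are embedded by classical (Torgerson) MDS of the
allele-sharing distance (per-pair mean |dosage difference| over shared
called loci). With two non-recombining clades this yields three collinear,
equidistant clusters on axis 1: clade-homozygotes at the ends, heterozygotes
in the middle. A 1-D three-component Gaussian mixture (EM, k-means
initialization, fixed seed) assigns SS/NS/NN; samples below a 0.95 posterior
are left unassigned. End clusters are polarized southern vs northern by the
majority population of origin of their members; if the majorities cannot
polarize the ends, heterozygosity at the region loci confirms only the
middle cluster and the call fails loudly rather than guessing. Degenerate
inputs (axis-1 eigenvalue share < 0.5, or k-means clusters separated by less
than twice their internal spread) degrade to a flagged 1–2-cluster report
with all samples unassigned.

This replaces the published-but-unreleased invclust internals with standard,
testable components producing the same three-cluster geometry.

The genome-wide PCA uses EIGENSOFT-style normalization (center by 2p̂, scale
by √(p̂(1−p̂)), per-locus mean imputation), with optional exclusion of loci
inside the divergent regions to show the populations are otherwise
inseparable.

### Geographic clines

Sites are projected orthogonally onto the great circle through the transect
endpoints (haversine geometry, R = 6371 km); the projection choice is this
package's, as is the 300-km off-axis warning threshold. Northern-haplotype
frequency along the transect follows the tail-free four-parameter sigmoid

    p(x) = pMin + (pMax − pMin) / (1 + exp(−4(x − c)/w)),

with width w the inverse maximum slope. Parameters are estimated by
maximizing the binomial log-likelihood with Nelder-Mead from nine
deterministic grid starts (log-width and logit-tail transforms keep the
search unconstrained); a fit to a reversed transect returns the mirrored
parameters, so fitted `p_min`/`p_max` denote the left/right tails rather
than an ordered pair. Flags mark non-convergence, width at the lower bound
(step-like data), unidentifiable width, and flat frequency profiles.

Uncertainty comes from a seeded parametric bootstrap (default 100–200
replicates) with **bias-corrected percentile** intervals: the bootstrap
distribution of the width is right-skewed and median-shifted, and in
calibration runs plain percentile intervals covered a true width of 249 km
in only ~85% of replicates, versus ~90–93% after bias correction (the
remaining shortfall reflects the small design — 20 sites × 30 diploids —
not the interval construction). ML + bootstrap replaces HZAR's MCMC by
design: same cline equation, deterministic machinery.

The neutral-diffusion yardstick is the Barton–Gale approximation
w_n = 2.51·σ·√T; with the conventional σ = 50 km and T = 100 generations it
gives 1,255 km, an order of magnitude wider than the fitted clines.

### Phenotype association

Associations are computed on site means (the migratory proxy, feather
δ¹⁵N, varies too much between individuals), restricted to males (the sexes
differ in size; unsexed birds are excluded). Wing, tarsus and bill-head
collapse to the first principal component of the standardized traits, sign
fixed so larger birds score positive. The statistic is a plain Pearson r,
optionally stratified by transect, reported only for strata with ≥ 3 sites
and non-degenerate variance; no multiple-testing correction is applied, as
the correlations are descriptive.

## Synthetic data: what it emulates, and what it does not

The generator is site-independent (infinite sites, free recombination
within clades) so the expectation of every target statistic is exact:

* **Neutral group** — S = 3θL segregating sites with Uniform(0,1)
  frequencies; E[2pq] = 1/3 gives E[π] = θ.
* **Two populations** — Balding–Nichols: ancestral p, population
  frequencies Beta(ap, a(1−p)) with a = (1−F)/F, so Var = F·p(1−p) and the
  expected Weir–Cockerham estimate is F.
* **Divergent region** — clade cores differ at sites drawn with per-site
  probability 2μT (no recombination between clades by construction);
  within-clade variation is *shared ancestral polymorphism* — one
  underlying frequency per site realized independently in each clade — so
  the site-level d_XY contribution (2u(1−u)) cancels against (πₓ+πᵧ)/2 and
  E[d_A] = 2μT exactly. A clade with higher θ receives extra private sites;
  each adds E[u²] = 1/3 net, so E[d_A] inflates by Δθ (e.g. d_A ≈ 0.007 in
  the default chr1/chr5 analogues where θ_N = 0.007 vs θ_S = 0.005).
* **Transects** — 74 sites equally spaced along two great-circle transects
  (40 "Sweden", 34 "Poland/Lithuania"); per site, region haplotype
  frequencies come from the configured sigmoid clines (chr1/chr5) or from a
  logistic in altitude and latitude (chr3); individuals draw clade pairs
  under Hardy–Weinberg, so hybrid-zone heterozygotes and mixed two-region
  genotype combinations emerge rather than being imposed.
* **Phenotypes** — site-mean δ¹⁵N is linear in the site's chr1 northern
  frequency with site and individual Gaussian noise; size traits load on a
  latent individual size factor plus a weak phenotype shift; color is a
  discretized 1–9 latent scale; ~93% of individuals are male.

Default parameters are the study conditions being emulated: background
F = 0.007 between 9+9 resequenced diploids, θ = 0.005 (northern clade 0.007
inside chr1/chr5), clade split 250,000 generations at μ = 10⁻⁸ per site per
generation (d_A = 0.005, i.e. ≈0.75–1.6 Myr over the default rate range),
cline widths within 249–688 km with 373 and 249 km on the second transect,
and an impurity plan leaving 8 southern and 6 northern resequenced samples
homozygous across all three regions. Sites per site-visit (14–16) make
~1,100 array samples. The default genome is scaled to ~4.6 Mb over five
scaffolds so the full pipeline completes in well under a minute of compute
per stage; acceptance simulations use 1 Mb regions, matching their stated
setups.

**What passing tests do not show about real data.** The generator has no
linkage disequilibrium within clades, no selection, no temporal cline
movement, and — deliberately — a Uniform(0,1) frequency spectrum rather
than a coalescent 1/x spectrum. Consequently Tajima's D on generator output
is slightly *positive*, not the negative values real resequencing data
show under population growth; the neutral-coalescent behaviour of the D
estimator is instead verified against msprime/tskit in the test suite.
Hardy–Weinberg clade pairing within sites is a modelling choice, not an
empirical claim about hybrid zones.

## Numerical choices

* Coordinates are 0-based half-open everywhere internally; VCF positions
  convert on read/write, so VCF position p falls in window (p−1)//size.
* QC defaults (quality ≥ 20, site missingness ≤ 0.2, depth within [⅓, 2]×
  the per-sample median, array MAF ≥ 0.01, locus/sample missingness ≤ 0.1)
  parameterize filters whose exact published thresholds are not available;
  per-sample depth mode marks aberrant calls missing so chronically bad
  sites fail on missingness, and an across-samples mode on site mean depth
  is provided as an alternative.
* Window ranking breaks F_ST ties by (scaffold, start); the top-1% count is
  ceil(0.01 × ranked windows).
* Partial terminal windows are emitted flagged and excluded from summaries
  by default (flag-controlled), since their inclusion convention is
  genuinely open.
* The weighted genome-wide F_ST pools numerators and denominators across
  all SNPs rather than averaging per-scaffold values.
* Monomorphic callable sites contribute 0 to every numerator and 1 to the
  callable denominator; positions outside the callable mask contribute to
  neither.
* All randomness flows from one numpy Generator per run; identical seeds
  reproduce byte-identical simulation output and numeric pipeline output.

## Known limitations

* The MDS genotyper assumes the three-cluster geometry; regions with
  substantial between-clade recombination would blur the clusters and push
  samples below the posterior threshold rather than produce wrong calls.
* Cline fits on environment-driven regions along a transect the
  environment does not follow are expected to flag as degenerate rather
  than estimate a meaningful width.
* Bootstrap coverage for the cline width is ~90–93% at the default design
  rather than the nominal 95% (see above); widening the design (more sites
  or larger per-site samples) restores nominal coverage.
* The divergence-time arithmetic inherits the full uncertainty of the
  yearly substitution rate; it is a range, not an estimate with a CI.
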