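# Methods

## The IBS2* statistic

For a pair of individuals, each autosomal biallelic locus where both
genotypes are called falls into one of four states: IBS0 (discordant
homozygotes, AA/BB), IBS1 (one shared allele), IBS2* (both heterozygous,
AB/AB) and concordant homozygotes (AA/AA, BB/BB).  IBS0 and IBS2* are
the *informative* states: both require the four alleles "two A, two B",
and conditional on that composition, Hardy–Weinberg sampling of four
independent alleles puts probability 1/3 on the IBS0 arrangement and 2/3
on IBS2* regardless of the allele frequency.  Genome-wide, for m
informative loci with s of them IBS2*, the IBS2*_ratio s/m therefore has
null expectation 2/3 for unrelated members of one population.

Any form of identity-by-descent suppresses IBS0 (an IBS0 locus must be
IBD0) faster than it suppresses IBS2*, raising the ratio; conversely,
allele-frequency differences between the two samples' source populations
and runs of homozygosity (which convert potential AB/AB loci into AB/AA
or AA/BB) lower it.

The test of ratio = 2/3 is the one-sample binomial-proportion Z-test,
z = (s/m − 2/3) / sqrt((2/3)(1/3)/m), with two-sided normal p-values and
Bonferroni correction over the number of pairs scanned.  An exact
binomial p-value is available as a cross-check; at cohort marker counts
the two agree essentially always (the suite requires ≥ 99% decision
agreement at m = 1000).  The percent-informative statistic
(IBS0 + IBS2*)/(IBS0 + IBS1 + IBS2) is reported alongside: it rises with
pair heterozygosity and separates identical pairs (whose informative
fraction collapses to their own heterozygosity) from parent–child pairs.

A ratio above 0.70 (configurable) is the empirical screen for candidate
relatedness.  Elevated ratios can also arise from atypically *high*
heterozygosity without any IBD sharing; the IBD estimates below
disambiguate the two causes.

## Windowed Bayesian IBD estimation

Concordant-homozygote and no-call loci carry no information here and are
removed.  The remaining loci form two per-chromosome tracks:

* **d0 track** = loci with state in {IBS0, IBS2*}; "events" are IBS0.
* **d12 track** = loci with state in {IBS1, IBS2*}; "events" are IBS1.

Each track is scanned in windows of 300 track-SNPs advanced by
window/3 (both configurable; chromosomes with fewer than half a window
of track-SNPs are skipped, and a trailing partial window of at least
half size is emitted, otherwise merged into its predecessor).

Within a d0-track window of n SNPs with k events, the event fraction has
expectation 1/3 under IBD0 (the conditional identity above) and ≈ 0
otherwise, where residual IBS0 arises only from genotyping error.  With
binomial likelihoods and prior P(IBD0) = 1/3,

P(D0 | S) = B(k; n, 1/3) π₀ / [B(k; n, 1/3) π₀ + B(k; n, ε) (1 − π₀)]

with ε = 0.01 by default.  On the d12 track the event fraction has
expectation c under IBD1 (see below) and ≈ 0 under IBD2, and the
remaining mass P(¬D0 | S) is split between IBD1 and IBD2 by the
analogous likelihood ratio B(k; n, c) vs B(k; n, ε) with equal
sub-priors.  All likelihoods are evaluated in log space; every window
posterior triple sums to 1 by construction.

### Reconciling the two tracks on the genome

The two tracks have different marker densities, so their windows span
different genomic lengths.  Window results are therefore mapped onto the
base-pair coordinate before combination: a P(D0) profile from the d0
track and a conditional IBD1/IBD2 split from the d12 track are combined
per position and integrated,

K_j = Σ_w P_w(D_j | S) · l_w / Σ_w l_w,

where l_w are the lengths of the piecewise-constant profile segments.
Positions outside d12 coverage use the equal sub-prior split (this
affects only chromosome-end slivers); positions outside d0 coverage are
excluded from the genome length.  K0 + K1 + K2 = 1 exactly.

### Overlap aggregation and boundary refinement

Because the two binomial rates in each comparison are far apart (1/3 or
c versus ε), a window straddling an IBD-state boundary votes for the
high-rate state as soon as a modest fraction (≈ 10–30% of its SNPs) lies
in the high-rate region.  Averaging overlapping windows does not remove
this: the transition in the averaged profile is centred on the
likelihood crossover, not on the true boundary, which inflates K0 and
deflates K2 by a few percent at sibling-like mixtures of states.

The default aggregation therefore proceeds in two steps: windows are
hard-called (posterior > 1/2), maximal runs of equal calls become
segments whose value is the median window posterior, and each boundary
between runs is relocated to the maximum-likelihood changepoint of the
per-SNP event sequence within the two straddling windows (split point
maximising the left-state plus right-state binomial log-likelihood).
On gene-dropped sibling pairs this cuts the mean absolute error of K2
against the realized truth about three-fold, and it leaves pairs without
internal state changes (identical, parent–child, unrelated) untouched.
The plain per-position averaging rule is available via
`IBDModelParams(refine_boundaries=False)`.

Known residual limitation: IBD segments too short to flip any window
call (roughly, shorter than the high-rate fraction threshold times the
window span — a few Mb at default density) are absorbed into the
surrounding state.  This leaves a small upward bias in K0 (~+0.02 for
siblings at the test marker density); it halves at window 150 and
doubles at window 600, which is why the default window stays at 300 and
why K1/K2 for close relatives are insensitive to the choice within
150–600.

### The parameter c

In an IBD1 region, a d12-track locus with B-allele frequency q (p+q = 1)
is IBS1 with probability 2pq and IBS2* with probability 1/2 − pq, so the
expected event fraction is f(p) = 2pq/(2pq + 1/2 − pq).  At p = 1/2 this
reaches its maximum 2/3; integrating f against a flat prior on p gives
0.479.  The default c = 0.518 comes from an empirical-Bayes weighting:
the probability that a locus shows variation at all in an IBD1 region is
P(O|p) = 1/2 + pq (the complement of the concordant-homozygote
probability 1/2 − pq), and updating the flat prior twice by this
observation event weights the integrand by P(O|p)², giving
c = 0.51852 ≈ 0.518.  c must exceed the error rate and cannot exceed
2/3; K1/K2 estimates are insensitive to c ≥ 0.25 (property-tested), so
the simple binomial model with a single c is used rather than a
beta-binomial over the frequency spectrum.

## Relationship classification

The classifier is a cascade over (K0, K1, K2), with IBS2*_ratio bands
used as corroborating evidence (deviations are recorded as rationale
codes rather than overriding the K-based call, keeping the assignment
monotone in K1):

| class          | rule                                               | typical ratio |
|----------------|----------------------------------------------------|---------------|
| identical      | K2 ≥ 0.9                                           | ≥ 0.99        |
| parent–child   | K1 ≥ 0.9 and K2 < 0.1                              | ≥ 0.99        |
| full sibling   | K1 ≥ 0.15, nearest centroid is (0.5, 0.25)         | 0.90–0.96     |
| second degree  | K1 ≥ 0.15, nearest centroid is (0.5, 0)            | ~0.8          |
| third degree   | K1 ≥ 0.15, nearest centroid is (0.25, 0)           | 0.70–0.75     |
| distant        | 1/32 ≤ K1 < 0.15                                   | ~0.67–0.72    |
| het artifact   | ratio > 0.70 but K1 < 1/32                         | —             |
| low-het outlier| ratio significantly < 2/3, pair het < cohort norm  | —             |
| unrelated      | otherwise                                          | ~2/3          |

Nearest-centroid assignment is Euclidean in the (K1, K2) plane.

The K1 floor of 1/32 = 0.03125 is the expected K1 of a 1/64th
relationship, the practical detection limit of the windowed approach;
K1 values below it are indistinguishable from background.  The
low-heterozygosity outlier call needs a cohort reference, taken by
default as the median pair heterozygosity of the scanned comparisons.
All thresholds live in one `ClassThresholds` object and are reported
with the output.

## The gene-dropping simulator

The simulator exists so that every estimator property can be checked
against exact truth.  It emulates a SNP-array cohort:

* **Genome**: 22 autosomes with GRCh37-proportional lengths; the
  desk-scale preset uses 10% lengths with ~50k markers (fast enough for
  test suites), the full-scale preset uses full lengths with ~872k
  markers.  Marker positions are uniform per chromosome; the map rate is
  1 cM/Mb.
* **Founders**: two haplotypes per founder, drawn under HWE from a
  B-allele-frequency spectrum, by default uniform on [0.05, 0.95] (a
  deliberate stand-in: real array spectra are platform-specific and the
  IBS2*_ratio is frequency-free under the null anyway; the spectrum is
  configurable).
* **Meiosis**: crossovers from a Poisson process at the map rate
  (Haldane, no interference), random start phase; founder-haplotype
  labels are transmitted through the same crossover realization as the
  alleles, so the per-marker IBD state of any pair — and the realized
  Cotterman coefficients, obtained by weighting each marker by its
  inter-marker Voronoi interval — is exact.
* **Noise**: genotyping errors flip to an adjacent genotype
  (AA↔AB↔BB, default rate 0.01 matching the estimator's ε), no-calls
  (default 0.005), and optional forced runs of homozygosity that copy
  one haplotype over the other within given intervals.

Built-in scenarios cover identical (technical replicate: one genotype
vector duplicated, noise applied independently to each copy),
parent–child, full/half siblings, avuncular, first cousins, a 1/64th
relationship (descendants two and three meioses below a founding sib
pair) and unrelated pairs.

What the simulator does **not** model: linkage disequilibrium between
markers, crossover interference, recombination hotspots, admixture or
population structure, sex chromosomes, and realistic array
ascertainment.  Passing tests therefore demonstrate correctness of the
statistics under the stated generative model, not robustness to every
property of real array data; on real cohorts, population mixture shifts
the ratio null below 2/3 (flagged, not corrected) and high-LD regions
make informative loci locally non-independent.

## Numerical and design notes

* Fixed-seed determinism everywhere; the CLI writes the full parameter
  fingerprint into every output header.
* On a ~2.9-Morgan desk-scale genome the *realized* coefficients of a
  single pair scatter widely around their pedigree expectation
  (sd ≈ 0.09 for sibling k2), so replicate means over ≥ 20 pairs are the
  meaningful recovery check; the suite checks both recovery of the
  expectation and agreement with per-replicate realized truth.
* Pairs with zero informative loci yield a null-statistic row, not a
  silent drop; estimation with no usable window raises a diagnostic
  error.
* Monomorphic markers are retained at parse time (they only ever produce
  concordant-homozygote or missing states and drop out of both tracks).
* Positions are 1-based internally (as in MAP files); exported window
  and truth segments are 0-based half-open (BED convention).
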