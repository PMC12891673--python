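# Methods

## Problem and model

The pipeline infers sex-specific river-barrier effects on dispersal from
non-invasively collected SNP genotypes. Its unit of inference is the
*first-order dyad*: a pair of individuals whose estimated relatedness
exceeds 0.4, interpreted as parent–offspring or full siblings (expected
r = 0.5, versus 0.25 for second-order kin). Because such pairs co-occurred
at some point, the straight segment between their spatial centers is a
lower bound on a realized dispersal track, and the number of rivers that
segment crosses, its length, and its orientation relative to a reference
line orthogonal to the rivers are the observables for the barrier tests.
Parent–offspring and full-sib dyads are deliberately not distinguished.

## Individual identification

Replicated fecal samples are clustered by allelic mismatch count: per locus
called in both samples, the mismatch is 2 minus the multiset intersection
of the allele pairs; samples with ≤ 12 mismatching alleles over the
85-locus panel are linked, and individuals are connected components of the
link graph. Single linkage over the full edge set makes the result
independent of input order, and the component rule reproduces the
tolerance semantics of standard genotype-matching tools without
reverse-engineering any specific implementation. The 12-allele tolerance
is applied jointly across all loci (no locus-wise rule). Records with
fewer than 60 of 85 called loci are excluded before matching, which
prevents spurious matches on near-empty genotypes. Consensus genotypes are
per-locus majority calls (ties → missing). Sex is male iff a strict
majority of member samples amplify at least one of four Y markers; exact
ties flag the individual sex-ambiguous and exclude it from sexed analyses.

## Relatedness

The Lynch & Ritland (1999) weighted regression estimator is used with each
individual of a pair as reference in turn and the two multilocus estimates
averaged, making the estimator exactly symmetric. Loci missing in either
genotype are skipped; pairs sharing fewer than 40 informative loci are
excluded (the minimum-loci rule is a documented convention — the estimator
itself does not prescribe one). Reference allele frequencies are estimated
from all consensus genotypes, including dyad members; monomorphic loci
carry no information and are dropped. With 85 biallelic loci at
frequencies 0.3–0.7 the estimator's sampling standard deviation for true
first-order pairs is roughly 0.07–0.12, so a threshold at 0.4 misses a
non-negligible tail: across synthetic worlds at default noise the pipeline
recovers about 85–92% of true first-order pairs, with false dyads rare
(≲ 5% of the dyad set). This is intrinsic to the marker panel, not to the
implementation, and is the reason the recovery test asserts ≥ 85%.

## Crossing geometry

A river counts as crossed when the dyad segment intersects its polyline an
odd number of times: even parity means the track returned to its starting
bank, which for a barrier analysis is not a crossing. Degeneracies are
resolved deterministically — an endpoint lying exactly on a polyline is
nudged 1 mm toward the segment's other endpoint before counting, and
collinear overlap contributes no intersections. Angles are measured
between undirected lines and folded to [0°, 90°]; ≤ 45° from the reference
line is direction class D1 ("orthogonal to rivers"), > 45° is D2. The
reference azimuth is a configuration input; when absent it defaults to the
mean river-segment azimuth (length-weighted, doubled-angle averaging)
plus 90°. Dyads with coinciding centers have no defined angle and are
excluded from direction analyses but retained for distance and crossing
counts.

## Statistical tests

Crossing proportions: Yates-corrected χ² on the 2×2 dyad table. The
multi-location analysis (individuals sampled at ≥ 2 locations, "crossed"
iff any pair of locations spans a river) uses Fisher's exact test with the
conditional-MLE odds ratio and exact 95% CI obtained by inverting the
noncentral hypergeometric conditional test (the convention of R's
`fisher.test`); the conditional likelihood is evaluated in log space over
its finite support because generic distribution methods proved numerically
fragile near odds = 1. Distances: one-way ANOVA and Tukey HSD
(studentized-range p-values, Tukey–Kramer SE for unequal n). Directions:
one-proportion score z against 0.5 — the squared statistic equals the
one-proportion χ², which reconciles the z-test/χ² notational ambiguity
common in field reports; females use the one-sided "less" alternative.
Angle distributions: two-sample Kolmogorov–Smirnov, on all dyads and
restricted to > 25 km dispersals (those most likely to have faced a
river). All tests are cross-checked against independent longhand
transcriptions in the test suite to 1e-8.

## Random-direction null

Each of 1,000 replicates draws starting points with replacement from the
pool of known female dispersers — operationalized as the members of
female–female dyads, both endpoints eligible, since these are the
identifiable female dispersers in the data — assigns the observed
distance multiset without replacement (a permutation), and draws uniform
directions. The summary statistics are the replicate mean, the empirical
2.5th percentile (linear interpolation), and a one-sample one-sided t-test
of replicate proportions exceeding the observed proportion. The observed
proportion compared against the null is the share of female–female dyads
with ≥ 1 crossing; which dyad member moved is unknowable, and pooling both
endpoints sidesteps the ambiguity.

When the observation process is confined to a bounded study area (always
true for the synthetic generator, whose settlements are rejected outside
the extent), an unconstrained null is biased low: simulated dispersals may
exit the area into river-free space while real settlements near borders
were forced inward. `simulate_null_crossings` therefore accepts an
optional extent and re-draws directions whose endpoint leaves it (stuck
start/distance pairs re-draw the start). Without an extent the procedure
is the plain random-direction null.

Two further properties of the percentile check, established by simulation
and encoded in the acceptance tests:

* *Type-I calibration* holds (≈ 2.5% of zero-aversion worlds fall below
  the 2.5th percentile) when the observed dyads are mutually independent,
  so the calibration study uses pedigrees with one mother–daughter dyad
  per family.
* With clustered pedigrees (several female–female dyads sharing a mother,
  hence a start point), observed crossing indicators are positively
  correlated and the observed proportion is over-dispersed relative to
  the resampled null; the percentile check then rejects somewhat more
  than nominally (measured ≈ 5–7% at ~1.9 dyads per family). This design
  effect is a property of the procedure itself — real dyad sets share
  individuals too — and should be kept in mind when reading the
  percentile statement for observational data.

Power: with female crossing aversion 0.8 and ≈ 200 female–female dyads the
deficit is detected (observed below the 2.5th percentile) in > 80% of
synthetic worlds.

## Spatial PCA

The allele-count matrix (0/1/2, missing mean-imputed per locus, columns
centered) is decomposed through H = Xᵀ(L + Lᵀ)X / (2n) with L the
row-normalized adjacency of the Delaunay triangulation over individual
centers. Each eigenvalue equals the product of its score's variance and
Moran's I over the symmetrized network, so the spectrum splits genetic
variation into global (positive, clines/patches) and local (negative)
structure. Eigenvector signs are fixed deterministically (largest-magnitude
loading positive). Duplicate coordinates are jittered (isotropic Gaussian,
default 1 m — negligible at landscape scale) until distinct; only
duplicates are touched. The global (local) Monte-Carlo test permutes
genotype rows against coordinates and uses the positive (absolute
negative) eigenvalue mass as statistic, with p = (1 + #{perm ≥ obs}) /
(1 + n_permutations). The permutation statistic is a documented stand-in
validated by calibration (type-I ≈ α on exchangeable data) rather than a
claim of identity with any particular legacy implementation. Fewer than 19
permutations cannot resolve p at the 0.05 level and are rejected.

## Synthetic generator

The generator emulates the study conditions with known ground truth:

* **Landscape** — a 250 × 200 km rectangle crossed by 3 west–east rivers
  spaced 50 km apart, built as sinusoidal perturbations (amplitude 8 km,
  wavelength 70 km, random phase) of parallel baselines; simplicity and
  pairwise disjointness are re-verified, not assumed. The reference line
  orthogonal to the rivers runs south–north (azimuth 0°).
* **Pedigree** — families of two Hardy–Weinberg parents and 1 + Poisson
  offspring with Mendelian transmission at 85 biallelic loci (frequencies
  drawn from U(0.3, 0.7)); offspring sexes Bernoulli(0.5).
* **Dispersal** — mothers uniform in the extent; fathers and offspring
  settle from the mother at a kernel distance in a uniform direction.
  Kernels are log-normal, male median 45 km (σ = 0.67) and female median
  18 km (σ = 0.69), chosen so the heavy-tailed means (≈ 56 and 23 km)
  match the scale of field reports in which standard deviations rival the
  means. Crossing aversion acts by rejection-resampling of settlement
  proposals whose segment crosses a river, so realized distance
  distributions remain comparable between sexes; out-of-extent proposals
  are always re-drawn, and settlement failure after a retry budget raises
  an error rather than looping.
* **Sampling noise** — 1 + Poisson(0.9) samples per individual; per-allele
  substitution error 0.005, per-locus missingness 0.05, coordinate jitter
  2 km (isotropic). The genotyping-error and dropout rates of the real
  assay panel are not published; these defaults are conventions of
  plausible magnitude, are flagged in the configuration, and the tests
  that depend on them say so. Sex markers (4 Y, amplifying only in males;
  3 X) are simulated without error.

What the generator does not emulate — habitat or resistance surfaces,
temporal dynamics (seasons, hibernation), mortality, age structure, or
spatially heterogeneous sampling effort. Passing tests therefore show that
the pipeline's statistics behave correctly under the stated generative
model, not that any particular field dataset satisfies that model.

## Numerical choices and problem sizes

Deterministic seeding throughout (numpy `default_rng`; stage sub-seeds
spawned from one master seed), so identical seeds give byte-identical
outputs including the JSON report. The test suite and the acceptance
script use moderate problem sizes chosen to make Monte-Carlo assertions
sharp at three standard errors: 10⁴+ segment cases for geometry, 500 pairs
per relatedness class, 120–200 synthetic worlds with 1,000-replicate nulls
for calibration and power, and 200 permutation-test runs for the sPCA
type-I rate.

## Known limitations

* The relatedness threshold cannot separate parent–offspring from full
  siblings, and misses true first-order pairs whose estimate falls below
  0.4 (≈ 8–15% at this panel size).
* Dyad segments are straight lines; real movement paths are not, so
  crossing counts are lower bounds at the path level.
* The percentile check of the null is anti-conservative under strong dyad
  clustering (see above); the t-test shares the limitation since replicate
  proportions are treated as an i.i.d. sample.
* Spatial PCA mean-imputation slightly shrinks structure when missingness
  is high.
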