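# riverkin

Do major rivers act as sex-specific barriers to dispersal? `riverkin` is a
reusable Python pipeline for answering that question from non-invasive
genetic sampling of a large mammal population — the motivating system is
brown bears genotyped from hunter-collected fecal samples in a study area
divided into four regions by three sub-parallel rivers. It takes a table of
noisy SNP sample genotypes with collection coordinates plus river polylines,
and produces individuals, first-order kin dyads, river-crossing and
direction statistics, a Monte-Carlo random-direction null, and spatial
genetic structure summaries. A first-class synthetic-data generator with
known ground truth (landscape, pedigree, sex-specific dispersal kernels,
genotyping noise) supports parameter-recovery and calibration testing.

## The analysis

1. **Individual identification.** Fecal samples carry genotyping error and
   missing loci, so replicated samples of one animal rarely match exactly.
   Samples are joined whenever their allelic mismatch count over the
   85-locus autosomal panel is ≤ 12, and individuals are the connected
   components (single linkage) of that match graph. Sex comes from Y/X
   marker amplification; an individual's location is the arithmetic mean of
   its sample coordinates.
2. **First-order dyads.** Pairwise relatedness is the Lynch & Ritland (1999)
   regression estimator: for reference alleles (a, b) and partner alleles
   (c, d) at a locus,

       r̂ = [p_a(δ_bc + δ_bd) + p_b(δ_ac + δ_ad) − 4 p_a p_b]
           / [(1 + δ_ab)(p_a + p_b) − 4 p_a p_b],

   combined across loci with the published informativeness weights and
   averaged over both reference orderings. Pairs with r̂ > 0.4 are
   first-order dyads (parent–offspring or full siblings, expectation 0.5;
   second-order relatives sit near 0.25). The straight line between dyad
   centers proxies a minimum dispersal track.
3. **Barrier statistics.** A river counts as crossed when the dyad segment
   intersects its polyline an odd number of times (endpoints on opposite
   banks). Crossing proportions of male–male vs female–female dyads are
   compared by Yates-corrected χ²; multiply-located individuals by Fisher's
   exact test (conditional-MLE odds ratio with exact CI); distances by
   ANOVA + Tukey HSD; direction classes D1 (≤ 45° from the reference line
   orthogonal to the rivers) vs D2 by one-proportion score z-tests; angle
   distributions by two-sample Kolmogorov–Smirnov tests (all dyads, and
   only long > 25 km dispersals).
4. **Random-direction null.** Are rare female crossings just a by-product of
   short female dispersal? Each of 1,000 replicates redraws the observed
   female–female dispersals with starting points resampled from known
   female dispersers, the exact observed distance multiset, and uniform
   directions; the observed crossing proportion is compared to the
   replicate distribution (one-sided t-test and the 2.5th percentile).
5. **Spatial PCA.** Genotypes are decomposed over a Delaunay neighbor
   network so each axis extremizes variance × Moran's I; positive
   eigenvalues capture global (clinal) structure, negative ones local
   structure. Monte-Carlo permutation tests give global/local p-values.

## Worked example

```python
import riverkin as rk
from riverkin.pipeline import PipelineConfig, run_analysis

kernel = rk.DispersalKernelSpec(female_crossing_aversion=0.9)
records, rivers, truth = rk.simulate_world(seed=7, n_families=100, kernel=kernel)
report = run_analysis(records, rivers, PipelineConfig(seed=3))

c = report["crossings"]
print(f"MM crossing {100*c['MM']['proportion_crossed']:.0f}%  "
      f"FF crossing {100*c['FF']['proportion_crossed']:.0f}%")
print(f"null mean {100*report['h1_null_simulation']['mean_proportion']:.1f}%  "
      f"below 2.5th pct: {report['h1_null_simulation']['observed_below_lower_2p5']}")
print({k: round(v, 1) for k, v in report["h2_anova"]["inputs"]["means_km"].items()})
```

prints (seed 7, 100 families, female crossing aversion 0.9):

```
MM crossing 55%  FF crossing 10%
null mean 23.9%  below 2.5th pct: True
{'FF': 24.5, 'MF': 50.7, 'MM': 62.7}
```

Read: 55% of male–male dispersals crossed a river against 10% of
female–female ones; under random directions with the same female distances
the null expects 24% crossings, and the observed 10% falls below the null's
2.5th percentile — female crossing avoidance, not short distances, explains
the deficit. Mean male–male dyad distance (63 km) is more than twice the
female–female mean (25 km).

The same analysis runs from files:

```bash
riverkin simulate --seed 7 --n-families 100 --female-aversion 0.9 --out-dir sim/
riverkin all --genotypes sim/genotypes.csv --rivers sim/rivers.geojson \
             --seed 3 --out-dir results/
```

which writes `report.json`, `individuals.csv`, `dyads.csv` and a genotype
matrix with river-band region labels for external multivariate tools.

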