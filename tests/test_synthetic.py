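import numpy as np
import pytest

from riverkin.geometry import rivers_crossed
from riverkin.records import MISSING, Panel
from riverkin.synthetic import (
    DispersalKernelSpec,
    DistanceKernel,
    LandscapeSpec,
    disperse_and_settle,
    generate_landscape,
    generate_population,
    sample_genotypes,
    simulate_world,
)

from oracles import polyline_self_or_pairwise_intersections


class TestLandscape:
    def test_no_rivers(self):
        rs = generate_landscape(LandscapeSpec(n_rivers=0), seed=0)
        assert len(rs) == 0
        assert rivers_crossed((0, 0), (100, 100), rs) == 0

    def test_straight_rivers_are_parallel_lines(self):
        spec = LandscapeSpec(meander_amplitude=0.0)
        rs = generate_landscape(spec, seed=0)
        assert len(rs) == 3
        for line in rs.lines:
            ys = {y for _, y in line.coords}
            assert len(ys) == 1
        # south-to-north ordering
        levels = [line.coords[0][1] for line in rs.lines]
        assert levels == sorted(levels)
        # a segment from band 1 to band 4 along the reference azimuth crosses 3
        assert rivers_crossed((100_000, 30_000), (100_000, 180_000), rs) == 3

    def test_meandering_rivers_simple_and_disjoint_by_brute_force(self):
        spec = LandscapeSpec(
            extent=(0, 0, 30_000, 20_000),
            n_rivers=2,
            river_spacing=6_000,
            meander_amplitude=500,
            meander_wavelength=8_000,
        )
        rs = generate_landscape(spec, seed=42)
        coords = [np.asarray(line.coords) for line in rs.lines]
        assert polyline_self_or_pairwise_intersections(coords) == 0

    def test_deterministic_given_seed(self):
        a = generate_landscape(LandscapeSpec(), seed=9)
        b = generate_landscape(LandscapeSpec(), seed=9)
        for la, lb in zip(a.lines, b.lines):
            assert np.array_equal(np.asarray(la.coords), np.asarray(lb.coords))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(
                LandscapeSpec(n_rivers=5, river_spacing=50_000), seed=0
            )
        with pytest.raises(ValueError):
            generate_landscape(
                LandscapeSpec(meander_amplitude=30_000, river_spacing=50_000), seed=0
            )


class TestPopulation:
    def test_pedigree_bookkeeping_one_family(self):
        truth = generate_population(1, 2, 10, 0.5, seed=0)
        rels = [rel for _, _, rel in truth.first_order_pairs]
        assert rels.count("FS") == 1
        assert rels.count("PO") == 4  # 2 offspring x 2 parents
        assert len(truth.first_order_pairs) == len(set(
            frozenset((a, b)) for a, b, _ in truth.first_order_pairs
        ))

    def test_mendelian_consistency(self):
        truth = generate_population(20, 3, 50, 0.4, seed=1)
        by_fam = {}
        for iid, ind in truth.individuals.items():
            by_fam.setdefault(ind.family, {})[ind.role] = by_fam.setdefault(
                ind.family, {}
            ).get(ind.role, [])
            by_fam[ind.family][ind.role].append(ind)
        for fam in by_fam.values():
            gm = fam["mother"][0].genotype
            gf = fam["father"][0].genotype
            for kid in fam.get("offspring", []):
                gk = kid.genotype
                # some pair of transmittable alleles must explain the child
                possible = np.zeros(len(gk), dtype=bool)
                for tm in (0, 1):
                    for tf in (0, 1):
                        ok_m = (gm == 1) | (gm == 2 * tm)
                        ok_f = (gf == 1) | (gf == 2 * tf)
                        possible |= ok_m & ok_f & (gk == tm + tf)
                assert possible.all()

    def test_heterozygosity_near_half_at_f_half(self):
        truth = generate_population(300, 0, 40, 0.5, seed=2)
        g = np.stack([i.genotype for i in truth.individuals.values()])
        het = (g == 1).mean()
        n = g.size
        se = np.sqrt(0.25 / n)
        assert abs(het - 0.5) < 3 * se

    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(ValueError):
            generate_population(2, 1, 5, 0.0, seed=0)
        with pytest.raises(ValueError):
            generate_population(2, 1, 5, 1.0, seed=0)


class TestDispersal:
    def test_full_female_aversion_means_no_female_crossings(self, straight_rivers):
        truth = generate_population(40, 2, 5, 0.5, seed=3)
        kernel = DispersalKernelSpec(female_crossing_aversion=1.0)
        disperse_and_settle(truth, straight_rivers, kernel, seed=4)
        female = [d for d in truth.dispersals if d.sex == "F"]
        assert female and all(d.n_rivers_crossed == 0 for d in female)

    def test_no_rivers_no_crossings(self):
        rivers = generate_landscape(LandscapeSpec(n_rivers=0), seed=0)
        truth = generate_population(20, 2, 5, 0.5, seed=5)
        disperse_and_settle(truth, rivers, DispersalKernelSpec(), seed=6)
        assert all(d.n_rivers_crossed == 0 for d in truth.dispersals)

    def test_equal_kernels_no_aversion_equal_crossing_rates(self, straight_rivers):
        k = DistanceKernel("lognormal", median_km=25.0, sigma=0.6)
        kernel = DispersalKernelSpec(male=k, female=k)
        rates = {"M": [], "F": []}
        for seed in range(4):
            truth = generate_population(150, 3, 2, 0.5, seed=seed)
            disperse_and_settle(truth, straight_rivers, kernel, seed=seed + 100)
            for d in truth.dispersals:
                rates[d.sex].append(d.n_rivers_crossed >= 1)
        pm, pf = np.mean(rates["M"]), np.mean(rates["F"])
        nm, nf = len(rates["M"]), len(rates["F"])
        pool = np.mean(rates["M"] + rates["F"])
        se = np.sqrt(pool * (1 - pool) * (1 / nm + 1 / nf))
        assert abs(pm - pf) < 3.5 * se

    def test_coordinates_inside_extent(self, meander_rivers):
        truth = generate_population(30, 2, 5, 0.5, seed=7)
        disperse_and_settle(truth, meander_rivers, DispersalKernelSpec(), seed=8)
        xmin, ymin, xmax, ymax = meander_rivers.extent
        for x, y in truth.coordinates.values():
            assert xmin <= x <= xmax and ymin <= y <= ymax


class TestSampling:
    def _placed_truth(self, seed=9, n_loci=20):
        rivers = generate_landscape(LandscapeSpec(), seed=seed)
        truth = generate_population(15, 2, n_loci, 0.5, seed=seed)
        disperse_and_settle(truth, rivers, DispersalKernelSpec(), seed=seed + 1)
        return truth

    def test_noiseless_sampling_reproduces_truth(self):
        truth = self._placed_truth()
        recs = sample_genotypes(truth, 1, error_rate=0, missing_rate=0, jitter_sd=0, seed=0)
        assert len(recs) == len(truth.individuals)
        for r in recs:
            iid = r.sample_id.rsplit("_s", 1)[0]
            assert np.array_equal(r.genotype, truth.individuals[iid].genotype)
            assert (r.x, r.y) == truth.coordinates[iid]
            assert r.y_positive == (truth.individuals[iid].sex == "M")

    def test_all_missing_records(self):
        truth = self._placed_truth()
        recs = sample_genotypes(truth, 1, error_rate=0, missing_rate=1.0, jitter_sd=0, seed=0)
        assert all((r.genotype == MISSING).all() for r in recs)

    def test_pairwise_mismatches_match_binomial_oracle(self):
        """Mean allele mismatches between two samples of one individual at
        error rate e: each of the 2L alleles independently flips with
        probability e, so compare against a direct flip simulation."""
        e, L = 0.01, 85
        truth = self._placed_truth(n_loci=L)
        # package path: replicated samples of the same individuals
        diffs = []
        for seed in range(30):
            recs = sample_genotypes(
                truth, 2, error_rate=e, missing_rate=0, jitter_sd=0, seed=seed
            )
            by_ind = {}
            for r in recs:
                by_ind.setdefault(r.sample_id.rsplit("_s", 1)[0], []).append(r)
            for a, b in ((v[0], v[1]) for v in by_ind.values() if len(v) == 2):
                diffs.append(int(np.abs(a.genotype - b.genotype).sum()))
        # oracle: direct per-allele flip simulation on random genotypes
        rng = np.random.default_rng(123)
        oracle_diffs = []
        for _ in range(3000):
            g = rng.integers(0, 3, L)

            def noisy(g):
                n1 = g.copy()
                f1 = rng.binomial(n1, e)
                f0 = rng.binomial(2 - n1, e)
                return n1 - f1 + f0

            oracle_diffs.append(int(np.abs(noisy(g) - noisy(g)).sum()))
        mean, omean = np.mean(diffs), np.mean(oracle_diffs)
        se = np.sqrt(np.var(diffs) / len(diffs) + np.var(oracle_diffs) / len(oracle_diffs))
        assert abs(mean - omean) < 3 * se
        # and both sit near the first-order expectation 2 * 2 * L * e
        assert abs(mean - 4 * L * e) < 0.5

    def test_identical_seeds_identical_outputs(self):
        a = simulate_world(seed=5, n_families=10)
        b = simulate_world(seed=5, n_families=10)
        assert len(a[0]) == len(b[0])
        for ra, rb in zip(a[0], b[0]):
            assert ra.sample_id == rb.sample_id
            assert (ra.x, ra.y) == (rb.x, rb.y)
            assert np.array_equal(ra.genotype, rb.genotype)
        for la, lb in zip(a[1].lines, b[1].lines):
            assert np.array_equal(np.asarray(la.coords), np.asarray(lb.coords))
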