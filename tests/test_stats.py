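import numpy as np
import pytest
from scipy import stats as sps
from shapely.geometry import LineString

from riverkin.geometry import RiverSet
from riverkin.records import Individual
from riverkin.stats import (
    angle_distribution_test,
    crossing_proportion_test,
    direction_proportion_test,
    distance_anova_tukey,
    fisher_exact_or,
    multilocation_crossing_table,
    simulate_null_crossings,
)

from oracles import (
    angular_hit_fraction_oracle,
    anova_oneway_oracle,
    fisher_p_enumeration_oracle,
    ks_two_sample_oracle,
    one_proportion_z_oracle,
    one_sample_t_oracle,
    tukey_hsd_oracle,
    yates_chi2_oracle,
)


class TestCrossingProportions:
    def test_hand_computed_yates_value(self):
        # table [[3,1],[1,3]]: all expected counts 2, sum (|O-E|-0.5)^2/E = 0.5
        assert crossing_proportion_test(3, 4, 1, 4).statistic == pytest.approx(0.5)

    def test_equal_proportions(self):
        rep = crossing_proportion_test(10, 20, 10, 20)
        stat, _ = yates_chi2_oracle([[10, 10], [10, 10]])
        assert rep.statistic == pytest.approx(stat)
        assert rep.statistic == 0.0

    def test_group_swap_symmetry(self):
        a = crossing_proportion_test(7, 30, 2, 25)
        b = crossing_proportion_test(2, 25, 7, 30)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_a, n_b = rng.integers(5, 200, 2)
            c_a, c_b = rng.integers(1, n_a), rng.integers(1, n_b)
            rep = crossing_proportion_test(c_a, n_a, c_b, n_b)
            stat, p = yates_chi2_oracle([[c_a, n_a - c_a], [c_b, n_b - c_b]])
            assert rep.statistic == pytest.approx(stat, abs=1e-8)
            assert rep.p_value == pytest.approx(p, abs=1e-8)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            crossing_proportion_test(0, 0, 1, 2)


class TestFisherExact:
    def test_multilocation_sex_table(self):
        """6/36 males vs 3/48 females with crossings."""
        res = fisher_exact_or([[6, 30], [3, 45]])
        assert res.odds_ratio == pytest.approx(2.96, abs=0.005)
        assert res.ci_low == pytest.approx(0.58, abs=0.005)
        assert res.ci_high == pytest.approx(19.70, abs=0.005)
        assert res.p_value == pytest.approx(0.16, abs=0.005)

    def test_balanced_table(self):
        res = fisher_exact_or([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0)

    def test_p_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = rng.integers(0, 12, (2, 2))
            if t.sum() == 0 or 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
                continue
            res = fisher_exact_or(t)
            assert res.p_value == pytest.approx(
                fisher_p_enumeration_oracle(t.tolist()), abs=1e-10
            )

    def test_boundary_counts(self):
        res = fisher_exact_or([[0, 10], [5, 5]])
        assert res.odds_ratio == 0.0 and res.ci_low == 0.0
        res = fisher_exact_or([[10, 0], [5, 5]])
        assert np.isinf(res.odds_ratio) and np.isinf(res.ci_high)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_or([[0, 0], [3, 4]])


class TestDistanceAnova:
    def test_identical_groups_f_zero_tukey_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        rep, tukey = distance_anova_tukey({"MM": g, "FF": g, "MF": g})
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert all(row["p_adj"] == pytest.approx(1.0) for row in tukey)

    def test_matches_longhand_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            groups = {
                k: rng.normal(rng.uniform(0, 50), 10, rng.integers(5, 40))
                for k in ("MM", "FF", "MF")
            }
            rep, tukey = distance_anova_tukey(groups)
            labels = sorted(groups)
            arrays = [groups[k] for k in labels]
            f, p = anova_oneway_oracle(arrays)
            assert rep.statistic == pytest.approx(f, abs=1e-8)
            assert rep.p_value == pytest.approx(p, abs=1e-8)
            oracle = tukey_hsd_oracle(arrays)
            for row in tukey:
                i, j = labels.index(row["group_a"]), labels.index(row["group_b"])
                assert row["p_adj"] == pytest.approx(oracle[(i, j)], abs=1e-8)

    def test_small_class_dropped(self):
        rng = np.random.default_rng(3)
        groups = {"MM": rng.normal(0, 1, 10), "FF": rng.normal(0, 1, 10), "MF": [1.0]}
        rep, _ = distance_anova_tukey(groups)
        assert rep.inputs["classes"] == ["FF", "MM"]


class TestDirectionProportion:
    def test_exactly_half(self):
        rep = direction_proportion_test(50, 100)
        assert rep.statistic == 0.0 and rep.p_value == pytest.approx(1.0)

    def test_matches_score_oracle_and_chi2_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(5, 400))
            k = int(rng.integers(0, n + 1))
            for alt in ("two-sided", "less"):
                rep = direction_proportion_test(k, n, alt)
                z, p = one_proportion_z_oracle(k, n, alternative=alt)
                assert rep.statistic == pytest.approx(z, abs=1e-8)
                assert rep.p_value == pytest.approx(p, abs=1e-8)
                assert rep.extra["chi2"] == pytest.approx(z * z, abs=1e-8)

    def test_extreme_deficit_close_to_exact_binomial(self):
        rep = direction_proportion_test(0, 20, "less")
        exact = sps.binom.cdf(0, 20, 0.5)  # 9.54e-7
        assert exact < rep.p_value < 100 * exact


class TestAngleKS:
    def test_identical_samples(self):
        a = np.linspace(0, 90, 30)
        rep = angle_distribution_test(a, a)
        assert rep.statistic == 0.0

    def test_fully_separated(self):
        rep = angle_distribution_test(np.full(10, 5.0), np.full(10, 85.0))
        assert rep.statistic == 1.0

    def test_matches_cdf_scan_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = rng.uniform(0, 90, rng.integers(5, 60))
            b = rng.uniform(0, 90, rng.integers(5, 60))
            rep = angle_distribution_test(a, b)
            assert rep.statistic == pytest.approx(ks_two_sample_oracle(a, b), abs=1e-12)

    def test_distance_filter_and_empty_error(self):
        a, b = np.array([10.0, 20.0]), np.array([70.0, 80.0])
        da, db = np.array([30.0, 10.0]), np.array([30.0, 40.0])
        rep = angle_distribution_test(a, b, da, db, min_distance_km=25.0)
        assert rep.inputs["n_a"] == 1 and rep.inputs["n_b"] == 2
        with pytest.raises(ValueError):
            angle_distribution_test(a, b, da, db, min_distance_km=100.0)


class TestNullSimulation:
    def test_no_rivers_all_zero(self):
        rs = RiverSet(names=[], lines=[], reference_azimuth_deg=0.0)
        res = simulate_null_crossings(
            np.array([[0.0, 0.0]]), [5.0, 7.0], rs, 2, observed_proportion=0.0,
            reps=25, seed=0,
        )
        assert np.all(res.replicate_proportions == 0.0)

    def test_distance_mismatch_rejected(self, one_river):
        with pytest.raises(ValueError):
            simulate_null_crossings(
                np.array([[0.0, 0.0]]), [5.0], one_river, 2,
                observed_proportion=0.0, reps=10, seed=0,
            )

    def test_short_distances_between_two_rivers_never_cross(self):
        rivers = RiverSet(
            names=["s", "n"],
            lines=[
                LineString([(-100_000, -10_000), (100_000, -10_000)]),
                LineString([(-100_000, 10_000), (100_000, 10_000)]),
            ],
            reference_azimuth_deg=0.0,
        )
        res = simulate_null_crossings(
            np.array([[0.0, 0.0]]), list(np.full(40, 4.0)), rivers, 40,
            observed_proportion=0.0, reps=40, seed=1,
        )
        assert np.all(res.replicate_proportions == 0.0)

    def test_long_distances_match_angular_hitting_oracle(self):
        """From a single midpoint start, the crossing probability over random
        directions is a pure angular measure, computable by dense
        integration for straight finite rivers."""
        levels = [-10_000.0, 10_000.0]
        x_range = (-60_000.0, 60_000.0)
        rivers = RiverSet(
            names=["s", "n"],
            lines=[LineString([(x_range[0], y), (x_range[1], y)]) for y in levels],
            reference_azimuth_deg=0.0,
        )
        d_km = 50.0
        n, reps = 100, 60
        res = simulate_null_crossings(
            np.array([[0.0, 0.0]]), list(np.full(n, d_km)), rivers, n,
            observed_proportion=0.0, reps=reps, seed=2,
        )
        expect = angular_hit_fraction_oracle((0.0, 0.0), d_km * 1000, levels, x_range)
        se = np.sqrt(expect * (1 - expect) / (n * reps))
        assert abs(res.mean_proportion - expect) < 4 * se

    def test_summaries_consistent_with_oracles(self, one_river):
        rng = np.random.default_rng(3)
        pool = rng.uniform(-5000, 5000, (20, 2))
        res = simulate_null_crossings(
            pool, list(rng.uniform(1, 20, 50)), one_river, 50,
            observed_proportion=0.1, reps=60, seed=3,
        )
        p = res.replicate_proportions
        assert res.mean_proportion == pytest.approx(p.mean())
        assert res.lower_2p5_percentile == pytest.approx(np.percentile(p, 2.5))
        t, pv = one_sample_t_oracle(p, 0.1)
        assert res.t_statistic == pytest.approx(t, abs=1e-8)
        assert res.one_sided_p == pytest.approx(pv, abs=1e-8)


class TestMultilocationTable:
    def _ind(self, iid, sex, locs):
        locs = np.asarray(locs, dtype=float)
        return Individual(
            individual_id=iid,
            sex=sex,
            member_sample_ids=[f"{iid}_{k}" for k in range(len(locs))],
            consensus=np.zeros(5, np.int8),
            locations=locs,
            center=tuple(locs.mean(axis=0)),
        )

    def test_opposite_banks_counted_and_any_pair_rule(self, one_river):
        inds = [
            self._ind("m1", "M", [(0, -500), (0, 500)]),            # crossed
            self._ind("m2", "M", [(0, 500), (100, 600)]),           # not
            self._ind("f1", "F", [(0, 300), (50, 300), (0, -300)]), # 1st-3rd pair crosses
            self._ind("f2", "F", [(0, 100)]),                       # single location: excluded
        ]
        table = multilocation_crossing_table(inds, one_river)
        assert table.tolist() == [[1, 1], [1, 0]]

    def test_all_single_location_warns_empty(self, one_river):
        inds = [self._ind("m1", "M", [(0, 100)])]
        table = multilocation_crossing_table(inds, one_river)
        assert table.sum() == 0
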