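"""Hypothesis tests for sex-specific barrier effects, and the
random-direction Monte-Carlo null for female crossing frequency.

The tests mirror a standard barrier-analysis battery: Yates-corrected
chi-square on crossing proportions of male-male vs female-female dyads,
Fisher's exact test (conditional maximum-likelihood odds ratio with exact
CI) on multiply-sampled individuals, one-way ANOVA with Tukey HSD on dyad
distances, one-proportion score z-tests on direction classes, and
two-sample Kolmogorov-Smirnov tests on dispersal-angle distributions.

The null model asks whether females cross rivers less often than expected
from their (short) dispersal distances alone: it re-simulates the observed
female-female dispersals with starting points resampled from known female
dispersers, the exact multiset of observed distances, and uniformly random
directions, then compares the observed crossing proportion against the
replicate distribution (one-sided t-test and the empirical 2.5th
percentile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .geometry import RiverSet, crossed_any_batch, rivers_crossed
from .records import Dyad, Individual

__all__ = [
    "TestReport",
    "FisherExactResult",
    "NullSimulationResult",
    "crossing_proportion_test",
    "fisher_exact_or",
    "distance_anova_tukey",
    "direction_proportion_test",
    "angle_distribution_test",
    "simulate_null_crossings",
    "multilocation_crossing_table",
]

logger = logging.getLogger(__name__)


@dataclass
class TestReport:
    """A single statistical test result."""

    name: str
    statistic: float
    p_value: float
    df: float | None = None
    alternative: str = "two-sided"
    inputs: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


@dataclass
class FisherExactResult:
    odds_ratio: float  # conditional MLE
    ci_low: float
    ci_high: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


@dataclass
class NullSimulationResult:
    replicate_proportions: np.ndarray
    mean_proportion: float
    lower_2p5_percentile: float
    observed_proportion: float
    t_statistic: float
    one_sided_p: float
    n_dyads_per_replicate: int
    seed: int


def crossing_proportion_test(
    n_crossed_a: int, n_a: int, n_crossed_b: int, n_b: int
) -> TestReport:
    """Yates-corrected chi-square comparing two crossing proportions."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group totals must be positive")
    if n_crossed_a > n_a or n_crossed_b > n_b:
        raise ValueError("crossed counts exceed totals")
    table = np.array(
        [[n_crossed_a, n_a - n_crossed_a], [n_crossed_b, n_b - n_crossed_b]]
    )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=True)
    return TestReport(
        name="yates_chi2_crossing_proportions",
        statistic=float(chi2),
        p_value=float(p),
        df=float(dof),
        inputs={
            "prop_a": n_crossed_a / n_a,
            "prop_b": n_crossed_b / n_b,
            "n_a": n_a,
            "n_b": n_b,
        },
    )


def fisher_exact_or(table) -> FisherExactResult:
    """Fisher's exact test on a 2x2 table with the conditional-MLE odds
    ratio and exact 95% CI (inversion of the noncentral hypergeometric
    conditional test, the convention of R's fisher.test)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    a = int(t[0, 0])
    row1 = int(t[0].sum())
    col1 = int(t[:, 0].sum())
    total = int(t.sum())
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        raise ValueError("a zero margin leaves the odds ratio undefined")
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)

    # noncentral hypergeometric probabilities over the finite support,
    # evaluated in log space for numerical robustness
    ks = np.arange(lo, hi + 1)
    log_base = (
        special.gammaln(row1 + 1) - special.gammaln(ks + 1) - special.gammaln(row1 - ks + 1)
        + special.gammaln(total - row1 + 1) - special.gammaln(col1 - ks + 1)
        - special.gammaln(total - row1 - col1 + ks + 1)
    )

    def probs(odds):
        logw = log_base + ks * np.log(odds)
        logw -= logw.max()
        w = np.exp(logw)
        return w / w.sum()

    def cond_mean(odds):
        return float(probs(odds) @ ks)

    if a == lo:
        or_cmle = 0.0
    elif a == hi:
        or_cmle = np.inf
    else:
        or_cmle = optimize.brentq(lambda o: cond_mean(o) - a, 1e-12, 1e12)
    ci_low = 0.0 if a == lo else optimize.brentq(
        lambda o: probs(o)[ks >= a].sum() - 0.025, 1e-12, 1e12
    )
    ci_high = np.inf if a == hi else optimize.brentq(
        lambda o: probs(o)[ks <= a].sum() - 0.025, 1e-12, 1e12
    )
    p = float(stats.fisher_exact(t)[1])
    return FisherExactResult(
        odds_ratio=float(or_cmle),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        table=((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1]))),
    )


def distance_anova_tukey(groups: dict[str, np.ndarray]) -> tuple[TestReport, list[dict]]:
    """One-way ANOVA of dyad distances on sex class, plus Tukey HSD.

    ``groups`` maps class label -> array of distances (km). Classes with
    fewer than 2 values are excluded with a warning. Returns the ANOVA
    report and a list of pairwise Tukey rows (labels, mean difference,
    adjusted p, 95% CI).
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    dropped = set(groups) - set(usable)
    if dropped:
        logger.warning("excluding classes with < 2 dyads from ANOVA: %s", sorted(dropped))
    if len(usable) < 2:
        raise ValueError("need >= 2 classes with >= 2 dyads each")
    labels = sorted(usable)
    arrays = [usable[k] for k in labels]
    f_stat, p = stats.f_oneway(*arrays)
    df_between = len(labels) - 1
    df_within = sum(len(a) for a in arrays) - len(labels)
    report = TestReport(
        name="anova_distance_by_class",
        statistic=float(f_stat),
        p_value=float(p),
        df=float(df_between),
        inputs={
            "classes": labels,
            "n": {k: int(len(usable[k])) for k in labels},
            "means_km": {k: float(usable[k].mean()) for k in labels},
            "sd_km": {k: float(usable[k].std(ddof=1)) for k in labels},
            "df_within": df_within,
        },
    )
    hsd = stats.tukey_hsd(*arrays)
    ci = hsd.confidence_interval(0.95)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff_km": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(hsd.pvalue[i, j]),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                }
            )
    return report, rows


def direction_proportion_test(
    n_d1: int, n_total: int, alternative: str = "two-sided"
) -> TestReport:
    """One-proportion score z-test of P(direction = D1) against 0.5.

    The squared statistic equals the one-proportion chi-square, so z^2 is
    reported alongside. ``alternative``: "two-sided" or "less" (fewer D1
    than chance).
    """
    if n_total < 1:
        raise ValueError("need at least one direction-classified dyad")
    if alternative not in ("two-sided", "less"):
        raise ValueError("alternative must be 'two-sided' or 'less'")
    phat = n_d1 / n_total
    z = (phat - 0.5) / np.sqrt(0.25 / n_total)
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = stats.norm.cdf(z)
    return TestReport(
        name="one_proportion_z_direction",
        statistic=float(z),
        p_value=float(p),
        alternative=alternative,
        inputs={"n_d1": n_d1, "n_total": n_total, "proportion_d1": phat},
        extra={"chi2": float(z * z)},
    )


def angle_distribution_test(
    angles_a,
    angles_b,
    distances_a=None,
    distances_b=None,
    min_distance_km: float = 0.0,
) -> TestReport:
    """Two-sample Kolmogorov-Smirnov test on dispersal-angle distributions.

    With ``min_distance_km`` > 0 (and distances supplied), only dyads whose
    distance exceeds the threshold enter the comparison — the long
    dispersals most likely to have faced a river.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if min_distance_km > 0.0:
        if distances_a is None or distances_b is None:
            raise ValueError("distance filter requested but distances not supplied")
        a = a[np.asarray(distances_a, dtype=float) > min_distance_km]
        b = b[np.asarray(distances_b, dtype=float) > min_distance_km]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            "no dyads left after the distance filter; lower min_distance_km "
            "or supply more dyads"
        )
    res = stats.ks_2samp(a, b)
    return TestReport(
        name="ks_angle_distributions",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        inputs={"n_a": int(len(a)), "n_b": int(len(b)), "min_distance_km": min_distance_km},
    )


def simulate_null_crossings(
    start_pool: np.ndarray,
    observed_distances_km,
    rivers: RiverSet,
    n_dyads: int,
    observed_proportion: float,
    reps: int = 1000,
    seed: int = 0,
    extent: tuple[float, float, float, float] | None = None,
) -> NullSimulationResult:
    """Random-direction null for the female crossing proportion.

    Each replicate draws ``n_dyads`` starting points with replacement from
    ``start_pool`` (coordinates of known female dispersers), assigns each the
    observed distances *without* replacement (a permutation, so every
    replicate reuses the exact observed distance multiset) and a uniform
    direction on [0, 360); the proportion of synthetic dispersals crossing at
    least one river is recorded. Summaries: replicate mean, empirical 2.5th
    percentile (linear interpolation), and a one-sample one-sided t-test of
    the replicate proportions being greater than the observed proportion.

    When ``extent`` is given, directions whose endpoint would fall outside
    it are re-drawn (and, for start/distance pairs with no feasible
    direction, the start is re-drawn), mirroring a study area in which every
    observed settlement necessarily lies inside the sampled region. Without
    it, simulated dispersals may leave the area, which biases the null
    toward fewer crossings when the real observation process is confined.
    """
    start_pool = np.asarray(start_pool, dtype=float).reshape(-1, 2)
    d_km = np.asarray(observed_distances_km, dtype=float)
    if len(d_km) != n_dyads:
        raise ValueError(
            f"n_dyads ({n_dyads}) must equal the number of observed distances ({len(d_km)})"
        )
    if len(start_pool) == 0:
        raise ValueError("empty start pool")
    if np.any(d_km <= 0):
        raise ValueError("observed distances must be positive")
    rng = np.random.default_rng(seed)
    props = np.empty(reps)
    for rep in range(reps):
        starts = start_pool[rng.integers(0, len(start_pool), n_dyads)]
        dists_m = rng.permutation(d_km) * 1000.0
        theta = rng.uniform(0.0, 2.0 * np.pi, n_dyads)
        ends = starts + np.column_stack(
            [dists_m * np.cos(theta), dists_m * np.sin(theta)]
        )
        if extent is not None:
            xmin, ymin, xmax, ymax = extent
            for round_ in range(500):
                bad = ~(
                    (ends[:, 0] >= xmin) & (ends[:, 0] <= xmax)
                    & (ends[:, 1] >= ymin) & (ends[:, 1] <= ymax)
                )
                if not bad.any():
                    break
                if round_ >= 50:  # start/distance pair may admit no direction
                    starts[bad] = start_pool[rng.integers(0, len(start_pool), bad.sum())]
                th = rng.uniform(0.0, 2.0 * np.pi, int(bad.sum()))
                ends[bad] = starts[bad] + np.column_stack(
                    [dists_m[bad] * np.cos(th), dists_m[bad] * np.sin(th)]
                )
            else:
                raise RuntimeError("could not keep simulated dispersals inside the extent")
        if len(rivers) == 0:
            props[rep] = 0.0
        else:
            props[rep] = crossed_any_batch(starts, ends, rivers).mean()
    if np.allclose(props, props[0]):
        # degenerate spread (e.g. no rivers): the t statistic is undefined
        t_stat, p = np.inf if props.mean() > observed_proportion else np.nan, np.nan
    else:
        t_stat, p = stats.ttest_1samp(props, observed_proportion, alternative="greater")
    return NullSimulationResult(
        replicate_proportions=props,
        mean_proportion=float(props.mean()),
        lower_2p5_percentile=float(np.percentile(props, 2.5)),
        observed_proportion=float(observed_proportion),
        t_statistic=float(t_stat),
        one_sided_p=float(p),
        n_dyads_per_replicate=n_dyads,
        seed=seed,
    )


def multilocation_crossing_table(
    individuals: list[Individual], rivers: RiverSet
) -> np.ndarray:
    """2x2 counts (rows: M, F; cols: crossed, not crossed) over individuals
    with >= 2 sampling locations; an individual "crossed" iff any unordered
    pair of its locations has at least one river crossing."""
    table = np.zeros((2, 2), dtype=np.int64)
    n_multi = 0
    for ind in individuals:
        if ind.sex not in ("M", "F") or len(ind.locations) < 2:
            continue
        n_multi += 1
        crossed = False
        locs = ind.locations
        for i in range(len(locs)):
            for j in range(i + 1, len(locs)):
                if np.all(locs[i] == locs[j]):
                    continue
                if len(rivers) and rivers_crossed(locs[i], locs[j], rivers) >= 1:
                    crossed = True
                    break
            if crossed:
                break
        row = 0 if ind.sex == "M" else 1
        table[row, 0 if crossed else 1] += 1
    if n_multi == 0:
        logger.warning("no multiply-located individuals; crossing table is empty")
    return table
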