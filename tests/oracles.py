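"""Independent, deliberately naive reference implementations used as oracles.

Each function here transcribes a textbook formula or brute-force procedure
in a code path separate from the package, so that agreement between the two
routes guards against transcription errors in either.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom, norm, studentized_range, t as t_dist, f as f_dist


# --- relatedness -----------------------------------------------------------

def lynch_ritland_oracle(gx, gy, p1, usable, min_shared=1):
    """Symbol-by-symbol transcription of the weighted regression estimator
    of pairwise relatedness, averaged over both reference orderings.

    Genotypes are 0/1/2 copies of allele "1" (-1 missing); ``p1`` is the
    frequency of allele "1" per locus.
    """

    def alleles(code):
        return {0: ("0", "0"), 1: ("0", "1"), 2: ("1", "1")}[code]

    def freq(locus, allele):
        return p1[locus] if allele == "1" else 1.0 - p1[locus]

    def one_way(ref, other):
        r_num = 0.0
        w_tot = 0.0
        for l in range(len(ref)):
            if ref[l] < 0 or other[l] < 0 or not usable[l]:
                continue
            a, b = alleles(ref[l])
            c, d = alleles(other[l])
            pa, pb = freq(l, a), freq(l, b)
            S = lambda u, v: 1.0 if u == v else 0.0
            numerator = pa * (S(b, c) + S(b, d)) + pb * (S(a, c) + S(a, d)) - 4 * pa * pb
            denominator = (1 + S(a, b)) * (pa + pb) - 4 * pa * pb
            r_locus = numerator / denominator
            weight = denominator / (2 * pa * pb)
            r_num += weight * r_locus
            w_tot += weight
        if w_tot == 0:
            return math.nan
        return r_num / w_tot

    shared = sum(
        1 for l in range(len(gx)) if gx[l] >= 0 and gy[l] >= 0 and usable[l]
    )
    if shared < min_shared:
        return math.nan
    return (one_way(gx, gy) + one_way(gy, gx)) / 2.0


# --- classical tests -------------------------------------------------------

def yates_chi2_oracle(table):
    """Sum over cells of (|O - E| - 0.5)^2 / E, the correction clamped so a
    cell's adjusted deviation cannot change sign."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    adj = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    stat = float((adj**2 / expected).sum())
    from scipy.stats import chi2

    return stat, float(chi2.sf(stat, 1))


def ks_two_sample_oracle(a, b):
    """Brute-force sup over the pooled points of |F_a - F_b|."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    pooled = np.concatenate([a, b])
    d = 0.0
    for x in pooled:
        fa = np.searchsorted(a, x, side="right") / len(a)
        fb = np.searchsorted(b, x, side="right") / len(b)
        d = max(d, abs(fa - fb))
    return d


def one_proportion_z_oracle(count, nobs, p0=0.5, alternative="two-sided"):
    """Score z-test: z = (p_hat - p0) / sqrt(p0 (1 - p0) / n)."""
    phat = count / nobs
    z = (phat - p0) / math.sqrt(p0 * (1 - p0) / nobs)
    if alternative == "two-sided":
        p = 2 * norm.sf(abs(z))
    elif alternative == "less":
        p = norm.cdf(z)
    else:
        p = norm.sf(z)
    return z, p


def anova_oneway_oracle(groups):
    """F from explicit between/within sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, float(f_dist.sf(f, df_b, df_w))


def tukey_hsd_oracle(groups):
    """Pairwise adjusted p-values from the studentized-range distribution,
    with the unequal-n (Tukey-Kramer) standard error."""
    k = len(groups)
    ns = [len(g) for g in groups]
    means = [np.mean(g) for g in groups]
    df_w = sum(ns) - k
    msw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups) / df_w
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
            q = abs(means[i] - means[j]) / se
            out[(i, j)] = float(studentized_range.sf(q, k, df_w))
    return out


def fisher_p_enumeration_oracle(table):
    """Two-sided Fisher p by exhaustive enumeration of tables with the
    observed margins: sum of hypergeometric probabilities <= P(observed)."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


def one_sample_t_oracle(sample, popmean):
    """One-sided (greater) one-sample t from the longhand formula."""
    sample = np.asarray(sample, dtype=float)
    n = len(sample)
    se = sample.std(ddof=1) / math.sqrt(n)
    t = (sample.mean() - popmean) / se
    return t, float(t_dist.sf(t, n - 1))


# --- geometry --------------------------------------------------------------

def segments_properly_intersect(p1, p2, q1, q2):
    """Orientation-test segment intersection (proper crossings only)."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if v == 0 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def polyline_self_or_pairwise_intersections(lines):
    """All-pairs brute-force segment intersection check over polylines.

    Returns the number of proper intersections between segments that are not
    adjacent within the same polyline.
    """
    segs = []
    for li, coords in enumerate(lines):
        coords = np.asarray(coords)
        for si in range(len(coords) - 1):
            segs.append((li, si, coords[si], coords[si + 1]))
    hits = 0
    for (la, sa, a1, a2), (lb, sb, b1, b2) in itertools.combinations(segs, 2):
        if la == lb and abs(sa - sb) <= 1:
            continue
        if segments_properly_intersect(a1, a2, b1, b2):
            hits += 1
    return hits


def side_change_crossings(p1, p2, river_xs, river_ys, n_steps=4000):
    """Dense sampling oracle: count sign changes of the side-of-river
    indicator along the segment, for a river that is a function of x."""
    ts = np.linspace(0.0, 1.0, n_steps)
    xs = p1[0] + ts * (p2[0] - p1[0])
    ys = p1[1] + ts * (p2[1] - p1[1])
    river_y = np.interp(xs, river_xs, river_ys)
    side = np.sign(ys - river_y)
    nz = side[side != 0]
    return int((np.diff(nz) != 0).sum())


def straight_band_oracle(point, river_levels):
    """Band index for straight horizontal rivers: rivers strictly south."""
    return int(sum(point[1] > y for y in river_levels))


def angular_hit_fraction_oracle(start, distance_m, river_levels, x_range, n_angles=20000):
    """Fraction of uniformly random directions whose segment crosses at
    least one straight horizontal river (level y, finite x extent)."""
    th = (np.arange(n_angles) + 0.5) / n_angles * 2 * np.pi
    ex = start[0] + distance_m * np.cos(th)
    ey = start[1] + distance_m * np.sin(th)
    hit = np.zeros(n_angles, dtype=bool)
    for yr in river_levels:
        dy = ey - start[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            tcross = (yr - start[1]) / dy
        valid = (dy != 0) & (tcross > 0) & (tcross < 1)
        xc = start[0] + tcross * (ex - start[0])
        hit |= valid & (xc >= x_range[0]) & (xc <= x_range[1])
    return hit.mean()
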