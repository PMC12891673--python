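"""Pairwise relatedness and first-order dyads.

Relatedness between consensus genotypes is estimated with the Lynch &
Ritland (1999) regression estimator: a locus-wise estimate referenced on one
individual of the pair, combined across loci with the published
informativeness weights, and averaged over the two possible reference
orderings so the result is symmetric. Population allele frequencies are
taken from all consensus genotypes.

Pairs whose estimate exceeds the first-order threshold (default r > 0.4,
chosen to separate parent-offspring/full-sib pairs, expectation 0.5, from
second-order relatives, expectation 0.25) become :class:`Dyad` objects
annotated with sex class, straight-line distance, dispersal angle relative
to the reference line, direction class, and rivers crossed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .geometry import (
    RiverSet,
    classify_direction,
    dispersal_angle_deg,
    dispersal_distance_km,
    rivers_crossed,
)
from .records import MISSING, Dyad, Individual

__all__ = [
    "AlleleFrequencies",
    "estimate_allele_frequencies",
    "lynch_ritland_r",
    "lynch_ritland_pairwise",
    "build_dyads",
]

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.4
DEFAULT_MIN_SHARED_LOCI = 40


@dataclass
class AlleleFrequencies:
    """Per-locus frequency of the a1 allele plus a usability mask.

    Loci that are monomorphic in the reference sample (or entirely missing)
    carry no relatedness information and are excluded via ``usable``.
    """

    p1: np.ndarray  # frequency of allele a1 per locus
    usable: np.ndarray  # bool per locus

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


def estimate_allele_frequencies(individuals: list[Individual]) -> AlleleFrequencies:
    """Empirical allele frequencies over non-missing consensus calls."""
    if len(individuals) < 2:
        raise ValueError("need >= 2 individuals to estimate allele frequencies")
    g = np.stack([ind.consensus for ind in individuals]).astype(np.float64)
    called = g != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p1 = np.where(called, g, 0.0).sum(axis=0) / (2.0 * n_called)
    usable = (n_called > 0) & (p1 > 0.0) & (p1 < 1.0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("excluding %d monomorphic/uncalled locus(i) from relatedness", n_dropped)
    p1 = np.where(usable, p1, np.nan)
    return AlleleFrequencies(p1=p1, usable=usable)


def _lr_one_reference(gx: np.ndarray, gy: np.ndarray, freqs: AlleleFrequencies) -> tuple[float, float]:
    """Locus-summed weighted numerator and weight, reference individual x.

    For reference alleles (a, b) with frequencies (pa, pb) and partner
    alleles (c, d), the locus estimate is

        r_l = [pa(d_bc + d_bd) + pb(d_ac + d_ad) - 4 pa pb]
              / [(1 + d_ab)(pa + pb) - 4 pa pb]

    with weight w_l equal to the denominator divided by 2 pa pb; the
    multilocus estimate is sum(w_l r_l) / sum(w_l).
    """
    num_sum = 0.0
    w_sum = 0.0
    for l in range(len(gx)):
        if gx[l] == MISSING or gy[l] == MISSING or not freqs.usable[l]:
            continue
        p1 = float(freqs.p1[l])
        p0 = 1.0 - p1
        a, b = (0, 0) if gx[l] == 0 else (0, 1) if gx[l] == 1 else (1, 1)
        c, d = (0, 0) if gy[l] == 0 else (0, 1) if gy[l] == 1 else (1, 1)
        pa = p0 if a == 0 else p1
        pb = p0 if b == 0 else p1
        dab, dac, dad = float(a == b), float(a == c), float(a == d)
        dbc, dbd = float(b == c), float(b == d)
        num = pa * (dbc + dbd) + pb * (dac + dad) - 4.0 * pa * pb
        den = (1.0 + dab) * (pa + pb) - 4.0 * pa * pb
        num_sum += num / (2.0 * pa * pb)
        w_sum += den / (2.0 * pa * pb)
    return num_sum, w_sum


def lynch_ritland_r(
    gx: np.ndarray,
    gy: np.ndarray,
    freqs: AlleleFrequencies,
    min_shared_loci: int = DEFAULT_MIN_SHARED_LOCI,
) -> float:
    """Symmetrized Lynch-Ritland relatedness of two consensus genotypes.

    Averages the weighted multilocus estimate over both reference orderings.
    Loci missing in either genotype (or unusable) are skipped; fewer than
    ``min_shared_loci`` shared informative loci raises ValueError.
    """
    gx = np.asarray(gx)
    gy = np.asarray(gy)
    shared = int(((gx != MISSING) & (gy != MISSING) & freqs.usable).sum())
    if shared < min_shared_loci:
        raise ValueError(
            f"only {shared} shared informative loci (< {min_shared_loci})"
        )
    nx, wx = _lr_one_reference(gx, gy, freqs)
    ny, wy = _lr_one_reference(gy, gx, freqs)
    return 0.5 * (nx / wx + ny / wy)


def _lr_tables(freqs: AlleleFrequencies) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus lookup tables for the vectorized estimator.

    A[l, gx * 3 + gy] = locus numerator / (2 pa pb), W[l, gx] = weight.
    """
    L = len(freqs.p1)
    A = np.zeros((L, 9))
    W = np.zeros((L, 3))
    geno_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    p1 = np.where(freqs.usable, freqs.p1, 0.5)  # placeholder; masked later
    for gx_code, (a, b) in geno_alleles.items():
        dab = float(a == b)
        pa = np.where(a == 0, 1.0 - p1, p1)
        pb = np.where(b == 0, 1.0 - p1, p1)
        W[:, gx_code] = ((1.0 + dab) * (pa + pb) - 4.0 * pa * pb) / (2.0 * pa * pb)
        for gy_code, (c, d) in geno_alleles.items():
            dac, dad = float(a == c), float(a == d)
            dbc, dbd = float(b == c), float(b == d)
            num = pa * (dbc + dbd) + pb * (dac + dad) - 4.0 * pa * pb
            A[:, gx_code * 3 + gy_code] = num / (2.0 * pa * pb)
    return A, W


def lynch_ritland_pairwise(
    genotypes: np.ndarray,
    freqs: AlleleFrequencies,
    pairs: np.ndarray,
    min_shared_loci: int = DEFAULT_MIN_SHARED_LOCI,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized symmetrized estimator for an array of index pairs.

    ``genotypes`` is (n, L) codes, ``pairs`` is (m, 2) integer indices.
    Returns (r, valid): r is NaN where a pair has fewer than
    ``min_shared_loci`` shared informative loci (valid False there).
    """
    A, W = _lr_tables(freqs)
    g = genotypes.astype(np.int64)
    L = g.shape[1]
    li = np.arange(L)
    r_out = np.full(len(pairs), np.nan)
    valid = np.zeros(len(pairs), dtype=bool)
    chunk = max(1, int(2e7 // max(1, L)))
    for s in range(0, len(pairs), chunk):
        pi = pairs[s : s + chunk]
        gi, gj = g[pi[:, 0]], g[pi[:, 1]]
        mask = (gi != MISSING) & (gj != MISSING) & freqs.usable[None, :]
        gic = np.clip(gi, 0, 2)
        gjc = np.clip(gj, 0, 2)
        a_xy = np.where(mask, A[li[None, :], gic * 3 + gjc], 0.0)
        a_yx = np.where(mask, A[li[None, :], gjc * 3 + gic], 0.0)
        w_x = np.where(mask, W[li[None, :], gic], 0.0)
        w_y = np.where(mask, W[li[None, :], gjc], 0.0)
        shared = mask.sum(axis=1)
        ok = shared >= min_shared_loci
        with np.errstate(invalid="ignore", divide="ignore"):
            r = 0.5 * (a_xy.sum(axis=1) / w_x.sum(axis=1) + a_yx.sum(axis=1) / w_y.sum(axis=1))
        r_out[s : s + chunk] = np.where(ok, r, np.nan)
        valid[s : s + chunk] = ok
    return r_out, valid


def build_dyads(
    individuals: list[Individual],
    freqs: AlleleFrequencies,
    rivers: RiverSet,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    min_shared_loci: int = DEFAULT_MIN_SHARED_LOCI,
) -> list[Dyad]:
    """All unordered pairs of sexed individuals with r > threshold, annotated.

    Sex-ambiguous individuals are excluded. Pairs with coinciding centers
    get an undefined angle/direction (None) but keep distance (0 km) and
    crossing count (0).
    """
    sexed = [ind for ind in individuals if ind.sex in ("M", "F")]
    if len(sexed) < 2:
        return []
    g = np.stack([ind.consensus for ind in sexed])
    pairs = np.array(list(itertools.combinations(range(len(sexed)), 2)), dtype=np.int64)
    r, valid = lynch_ritland_pairwise(g, freqs, pairs, min_shared_loci)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("excluded %d pair(s) with too few shared loci", n_excluded)
    dyads: list[Dyad] = []
    for (i, j), rij, ok in zip(pairs, r, valid):
        if not ok or not rij > r_threshold:
            continue
        a, b = sexed[i], sexed[j]
        if a.individual_id > b.individual_id:
            a, b = b, a
        sex_class = {"MM": "MM", "FF": "FF"}.get(a.sex + b.sex, "MF")
        dist = dispersal_distance_km(a.center, b.center)
        if dist > 0.0:
            angle = dispersal_angle_deg(a.center, b.center, rivers.reference_azimuth_deg)
            direction = classify_direction(angle)
            n_cross = rivers_crossed(a.center, b.center, rivers) if len(rivers) else 0
        else:
            angle, direction, n_cross = None, None, 0
        dyads.append(
            Dyad(
                id_a=a.individual_id,
                id_b=b.individual_id,
                sex_class=sex_class,
                r=float(rij),
                distance_km=dist,
                angle_deg=angle,
                direction=direction,
                rivers_crossed=n_cross,
            )
        )
    return dyads
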