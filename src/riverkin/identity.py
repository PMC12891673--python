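"""Collapse replicated noisy samples into individuals.

Non-invasively collected fecal samples yield several genotypes per animal,
each with genotyping error and missing loci. Samples are matched by allelic
mismatch count with a tolerance (default 12 mismatching alleles over the
85-locus panel) and clustered by single linkage: two samples belong to the
same individual whenever a chain of pairwise matches connects them. The
clustering is computed from the full thresholded mismatch graph (connected
components), so it is independent of input order.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .records import MISSING, Individual, SampleRecord

__all__ = [
    "allele_mismatch_count",
    "mismatch_matrix",
    "cluster_samples",
    "consensus_genotype",
    "assign_sex",
    "spatial_center",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 12
DEFAULT_MIN_COMPARABLE_LOCI = 60


def allele_mismatch_count(a: SampleRecord, b: SampleRecord) -> tuple[int, int]:
    """(mismatching alleles, comparable loci) between two sample genotypes.

    A locus is comparable when called in both samples; its mismatch count is
    2 minus the size of the multiset intersection of the two allele pairs,
    which for biallelic codes is simply |code_a - code_b| (0, 1 or 2).
    """
    ga, gb = a.genotype, b.genotype
    if ga.shape != gb.shape:
        raise ValueError("samples come from different panels (locus counts differ)")
    both = (ga != MISSING) & (gb != MISSING)
    mism = int(np.abs(ga[both].astype(np.int64) - gb[both]).sum())
    return mism, int(both.sum())


def mismatch_matrix(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (mismatches, comparable loci) for an (n, L) code matrix."""
    g = genotypes.astype(np.int16)
    called = g != MISSING
    n = len(g)
    mism = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    # row-chunked to bound the broadcast temporaries
    chunk = max(1, int(4e7 // max(1, n * g.shape[1])))
    for i0 in range(0, n, chunk):
        i1 = min(n, i0 + chunk)
        both = called[i0:i1, None, :] & called[None, :, :]
        diff = np.abs(g[i0:i1, None, :] - g[None, :, :])
        mism[i0:i1] = np.where(both, diff, 0).sum(axis=2)
        comp[i0:i1] = both.sum(axis=2)
    return mism, comp


def consensus_genotype(members: list[SampleRecord]) -> np.ndarray:
    """Per-locus majority call among non-missing member calls; ties and
    all-missing loci become missing."""
    g = np.stack([m.genotype for m in members]).astype(np.int64)
    n_loci = g.shape[1]
    out = np.full(n_loci, MISSING, dtype=np.int8)
    counts = np.stack([(g == code).sum(axis=0) for code in (0, 1, 2)])  # (3, L)
    top = counts.max(axis=0)
    winner = counts.argmax(axis=0)
    unique_top = (counts == top).sum(axis=0) == 1
    ok = (top > 0) & unique_top
    out[ok] = winner[ok]
    return out


def assign_sex(members: list[SampleRecord]) -> str:
    """"M" iff a strict majority of members shows >= 1 amplifying Y marker,
    "F" for a strict majority of Y-negative members, else "ambiguous"."""
    ypos = sum(m.y_positive for m in members)
    yneg = len(members) - ypos
    if ypos > yneg:
        return "M"
    if yneg > ypos:
        return "F"
    return "ambiguous"


def spatial_center(locations: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean of sampling coordinates (the individual's center)."""
    locations = np.asarray(locations, dtype=float)
    if locations.size == 0:
        raise ValueError("cannot compute the spatial center of zero locations")
    c = locations.reshape(-1, 2).mean(axis=0)
    return float(c[0]), float(c[1])


def cluster_samples(
    records: list[SampleRecord],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_comparable_loci: int = DEFAULT_MIN_COMPARABLE_LOCI,
) -> tuple[list[Individual], dict[str, str]]:
    """Identify individuals by single-linkage matching of sample genotypes.

    Records with fewer than ``min_comparable_loci`` called loci are excluded
    (and logged). Remaining records are joined whenever their allelic
    mismatch count is <= ``max_mismatch``; connected components of that graph
    are the individuals. Returns the individuals (ids assigned in order of
    each cluster's first sample) and the sample_id -> individual_id map.
    """
    kept = [r for r in records if r.n_called >= min_comparable_loci]
    dropped = [r.sample_id for r in records if r.n_called < min_comparable_loci]
    if dropped:
        logger.warning(
            "excluded %d sample(s) below %d called loci: %s",
            len(dropped), min_comparable_loci, ", ".join(dropped[:10]),
        )
    if not kept:
        raise ValueError("no samples pass the min_comparable_loci filter")

    g = np.stack([r.genotype for r in kept])
    mism, _comp = mismatch_matrix(g)
    n = len(kept)
    ii, jj = np.nonzero(np.triu(mism <= max_mismatch, k=1))
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)

    # stable individual ids: order of first appearance in the input
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    individuals: list[Individual] = []
    sample_map: dict[str, str] = {}
    for lab in sorted(set(labels), key=lambda l: order[l]):
        members = [kept[i] for i in np.nonzero(labels == lab)[0]]
        iid = f"IND{order[lab]:05d}"
        locs = np.array([[m.x, m.y] for m in members])
        individuals.append(
            Individual(
                individual_id=iid,
                sex=assign_sex(members),
                member_sample_ids=[m.sample_id for m in members],
                consensus=consensus_genotype(members),
                locations=locs,
                center=spatial_center(locs),
            )
        )
        for m in members:
            sample_map[m.sample_id] = iid
    return individuals, sample_map
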