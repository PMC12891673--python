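"""Spatial PCA of genotypes over a Delaunay connection network.

Ordinary PCA of an allele-count matrix finds axes of maximal genetic
variance; spatial PCA instead extremizes the product of variance and
Moran's I over a spatial weight network, so positive eigenvalues capture
*global* structure (clines, patches: neighbors more similar than random
pairs) and negative eigenvalues *local* structure (neighbors more
dissimilar). The decomposition used here is the eigenanalysis of the
symmetrized spatially lagged covariance H = X' (L + L')/2 X / n, where X is
the column-centered allele-count matrix and L the row-normalized Delaunay
adjacency.

Global and local Monte-Carlo tests permute genotype rows against
coordinates and compare the observed positive (resp. negative) eigenvalue
mass to the permutation distribution; p = (1 + #{perm >= obs}) /
(1 + n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import Delaunay, QhullError

__all__ = ["ConnectionNetwork", "SpcaResult", "build_network", "spca", "global_local_tests"]


@dataclass
class ConnectionNetwork:
    """Delaunay neighbor graph with row-normalized spatial weights."""

    coords: np.ndarray  # (n, 2), after any jitter
    edges: np.ndarray  # (m, 2) undirected, i < j
    weights: csr_matrix  # row-normalized adjacency L
    jitter_applied: bool

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def symmetric_weights(self) -> csr_matrix:
        return (self.weights + self.weights.T) * 0.5


def build_network(coords: np.ndarray, jitter_sd: float = 1.0, seed: int = 0) -> ConnectionNetwork:
    """Delaunay triangulation network over (possibly jittered) coordinates.

    Duplicate-coordinate points are unusable for triangulation, so jitter
    (isotropic Gaussian, default sd 1 m — negligible at landscape scale) is
    applied to duplicates only, re-drawn until all coordinates are distinct.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2).copy()
    n = len(coords)
    if n < 3:
        raise ValueError("need >= 3 points for a Delaunay network")
    rng = np.random.default_rng(seed)
    jittered = False
    for _ in range(100):
        _, first = np.unique(coords, axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(n), first)
        if len(dup) == 0:
            break
        jittered = True
        coords[dup] += rng.normal(0.0, jitter_sd, (len(dup), 2))
    else:
        raise RuntimeError("could not resolve duplicate coordinates by jitter")
    try:
        tri = Delaunay(coords)
    except QhullError as e:
        raise ValueError(f"Delaunay triangulation failed (collinear points?): {e}") from e
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            edges.add((min(a, b), max(a, b)))
    edge_arr = np.array(sorted(edges), dtype=np.int64)
    rows = np.concatenate([edge_arr[:, 0], edge_arr[:, 1]])
    cols = np.concatenate([edge_arr[:, 1], edge_arr[:, 0]])
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    weights = csr_matrix((inv[rows], (rows, cols)), shape=(n, n))
    return ConnectionNetwork(coords=coords, edges=edge_arr, weights=weights, jitter_applied=jittered)


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray  # signed, descending
    scores: np.ndarray  # (n, k) individual scores
    axis_variance: np.ndarray
    axis_moran: np.ndarray
    global_p: float | None = None
    local_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def _prepare_matrix(genotype_matrix: np.ndarray) -> np.ndarray:
    """Mean-impute missing allele counts per locus, then center columns."""
    X = np.asarray(genotype_matrix, dtype=float).copy()
    X[X < 0] = np.nan  # integer-coded missing
    nan_cols = np.all(np.isnan(X), axis=0)
    X[:, nan_cols] = 0.0
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.broadcast_to(col_mean, X.shape)[nan_mask]
    return X - X.mean(axis=0)


def _signed_eigh(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(H)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for k in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[i, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return vals, vecs


def spca(genotype_matrix: np.ndarray, network: ConnectionNetwork) -> SpcaResult:
    """Spatial PCA of an (individuals x loci) allele-count matrix.

    Missing counts (negative codes or NaN) are mean-imputed per locus. Each
    axis k satisfies lambda_k = var(score_k) * I(score_k): the eigenvalue is
    the product of the score's variance and its Moran's I over the
    symmetrized network, so the leading (trailing) axes are the most global
    (most local) combinations of loci.
    """
    X = _prepare_matrix(genotype_matrix)
    n = len(X)
    if n != network.n_nodes:
        raise ValueError("genotype matrix and network sizes differ")
    W = network.symmetric_weights()
    H = X.T @ (W @ X) / n
    vals, vecs = _signed_eigh(H)
    scores = X @ vecs
    ss = (scores**2).sum(axis=0)
    variance = ss / n
    with np.errstate(invalid="ignore", divide="ignore"):
        moran = np.einsum("nk,nk->k", scores, W @ scores) / ss
    moran = np.where(ss > 1e-12, moran, 0.0)
    return SpcaResult(
        eigenvalues=vals,
        scores=scores,
        axis_variance=variance,
        axis_moran=moran,
    )


def _eig_mass(X: np.ndarray, W: csr_matrix, n: int) -> tuple[float, float]:
    vals = np.linalg.eigvalsh(X.T @ (W @ X) / n)
    return float(vals[vals > 0].sum()), float(-vals[vals < 0].sum())


def global_local_tests(
    genotype_matrix: np.ndarray,
    network: ConnectionNetwork,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo tests for global and local spatial genetic structure.

    The test statistic is the positive (global) or absolute negative
    (local) eigenvalue mass of the sPCA decomposition; genotype rows are
    permuted against coordinates. Returns (global_p, local_p), each
    (1 + #{perm >= obs}) / (1 + n_permutations).
    """
    if n_permutations < 19:
        raise ValueError("n_permutations < 19 cannot resolve p at the 0.05 level")
    X = _prepare_matrix(genotype_matrix)
    n = len(X)
    if n != network.n_nodes:
        raise ValueError("genotype matrix and network sizes differ")
    W = network.symmetric_weights()
    obs_global, obs_local = _eig_mass(X, W, n)
    rng = np.random.default_rng(seed)
    ge = le = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pg, pl = _eig_mass(X[perm], W, n)
        ge += pg >= obs_global
        le += pl >= obs_local
    return (1 + ge) / (1 + n_permutations), (1 + le) / (1 + n_permutations)
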