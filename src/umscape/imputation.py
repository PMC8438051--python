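"""Diffusion-based denoising of normalized expression.

A k-NN graph over PC space is converted to affinities with an adaptive
(anisotropic) Gaussian kernel whose per-cell bandwidth is the distance to
the ka-th neighbor, symmetrized, row-normalized into a Markov transition
matrix M, and expression is smoothed as M^t X. Conservative defaults
t=3, k=27, ka=12 on the first 20 library-size-regressed PCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors

from .qc import NormalizedMatrix, pca_libsize_regressed


@dataclass
class AffinityGraph:
    matrix: sp.csr_matrix
    k: int
    ka: int
    symmetrized: bool


@dataclass
class MarkovMatrix:
    matrix: sp.csr_matrix

    def __post_init__(self):
        rows = np.asarray(self.matrix.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("rows of a Markov matrix must sum to 1")


def adaptive_affinity(pcs, k: int = 27, ka: int = 12, symmetrize: bool = True) -> AffinityGraph:
    """Adaptive-kernel affinities over the k-NN edge set.

    For cell i with scale sigma_i = distance to its ka-th neighbor,
    affinity(i, j) = exp(-d(i,j)^2 / sigma_i^2) for j among i's k nearest
    neighbors; the diagonal is zero; optionally symmetrized as (A + A^T)/2.
    """
    X = np.asarray(pcs, dtype=float)
    n = X.shape[0]
    if not (1 <= ka <= k <= n - 1):
        raise ValueError(f"need 1 <= ka <= k <= n-1, got k={k}, ka={ka}, n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dists, idx = nn.kneighbors(X)
    dists, idx = dists[:, 1:], idx[:, 1:]  # drop self

    sigma = dists[:, ka - 1].copy()
    if np.any(sigma == 0):
        warnings.warn("duplicate points: substituting smallest positive neighbor distance")
        global_pos = dists[dists > 0]
        fallback = global_pos.min() if global_pos.size else 1.0
        for i in np.nonzero(sigma == 0)[0]:
            pos = dists[i][dists[i] > 0]
            sigma[i] = pos.min() if pos.size else fallback

    vals = np.exp(-(dists**2) / sigma[:, None] ** 2)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((vals.ravel(), (rows, idx.ravel())), shape=(n, n))
    A.setdiag(0.0)
    A.eliminate_zeros()
    if symmetrize:
        A = (A + A.T) * 0.5
    return AffinityGraph(matrix=A.tocsr(), k=k, ka=ka, symmetrized=symmetrize)


def markov_normalize(aff: AffinityGraph | sp.spmatrix, cell_ids=None) -> MarkovMatrix:
    """Row-normalize an affinity matrix into a Markov transition matrix."""
    A = aff.matrix if isinstance(aff, AffinityGraph) else sp.csr_matrix(aff)
    rows = np.asarray(A.sum(axis=1)).ravel()
    if np.any(rows <= 0):
        bad = int(np.nonzero(rows <= 0)[0][0])
        name = cell_ids[bad] if cell_ids is not None else f"cell index {bad}"
        raise ValueError(f"isolated cell with zero affinity row: {name}")
    D_inv = sp.diags(1.0 / rows)
    return MarkovMatrix((D_inv @ A).tocsr())


@dataclass
class ImputedMatrix:
    values: np.ndarray
    provenance: dict = field(default_factory=dict)
    cell_ids: list[str] | None = None
    gene_ids: list[str] | None = None


def impute_diffusion(norm, markov: MarkovMatrix, t: int = 3) -> ImputedMatrix:
    """t-step diffusion of expression: output = M^t X, computed as t
    successive sparse multiplications (M^t is never densified)."""
    if t < 0:
        raise ValueError("diffusion time t must be >= 0")
    is_nm = isinstance(norm, NormalizedMatrix)
    X = np.array(norm.values if is_nm else norm, dtype=float, copy=True)
    M = markov.matrix
    for _ in range(t):
        X = M @ X
    return ImputedMatrix(
        values=X,
        provenance={"t": t},
        cell_ids=norm.cell_ids if is_nm else None,
        gene_ids=norm.gene_ids if is_nm else None,
    )


class DiffusionImputer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer for diffusion imputation.

    fit(X, library_size=..., graph_space=...) builds the Markov matrix on
    the first ``n_pcs`` library-size-regressed PCs of X (or on a supplied
    embedding); transform(X) smooths the same cells' expression by M^t.
    The graph is tied to the fitted cells, so transform requires a matrix
    with the same number of rows.
    """

    def __init__(self, k: int = 27, ka: int = 12, t: int = 3, n_pcs: int = 20,
                 random_state: int = 0):
        self.k = k
        self.ka = ka
        self.t = t
        self.n_pcs = n_pcs
        self.random_state = random_state

    def fit(self, X, y=None, library_size=None, graph_space=None):
        X = np.asarray(X, dtype=float)
        if graph_space is None:
            graph_space = pca_libsize_regressed(
                X, library_size=library_size, n_pcs=self.n_pcs, seed=self.random_state
            ).scores
        self.affinity_ = adaptive_affinity(graph_space, k=self.k, ka=self.ka)
        self.markov_ = markov_normalize(self.affinity_)
        self.n_cells_ = X.shape[0]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.n_cells_:
            raise ValueError("transform expects the matrix the graph was fitted on")
        return impute_diffusion(X, self.markov_, t=self.t).values


def impute(
    norm: NormalizedMatrix,
    library_size=None,
    k: int = 27,
    ka: int = 12,
    t: int = 3,
    n_pcs: int = 20,
    seed: int = 0,
) -> ImputedMatrix:
    """One-call convenience: graph on library-size-regressed PCs, then M^t X."""
    est = DiffusionImputer(k=k, ka=ka, t=t, n_pcs=n_pcs, random_state=seed)
    est.fit(norm.values, library_size=library_size)
    out = impute_diffusion(norm, est.markov_, t=t)
    out.provenance.update({"k": k, "ka": ka, "n_pcs": n_pcs})
    return out
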