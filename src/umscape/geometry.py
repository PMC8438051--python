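"""Diffusion maps, multi-scale diffusion distances, principal convex hull
(archetypal) analysis, archetype neighborhoods and EMD marker scoring.

The diffusion map eigendecomposes the row-stochastic Markov matrix of the
adaptive-kernel cell graph (built on PCs of the normalized, un-imputed
expression). Distances between cells sum squared diffusion-component
differences weighted either by the multi-scale factor lambda/(1-lambda)
(the geometric series over all diffusion times) or by lambda^t at a single
diffusion time t.

PCHA factorizes X ~ X C S with C and S column-stochastic (C relaxed by
delta), so archetypes Z = X^T C lie on the data's convex hull and cells are
convex mixtures of archetypes. The alternating projected-gradient solver
only accepts steps that decrease the squared reconstruction error, making
the objective monotone non-increasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.stats import wasserstein_distance
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import FitError, check_random_state, knee_point
from .imputation import adaptive_affinity, markov_normalize


# ---------------------------------------------------------------------------
# diffusion maps


class DiffusionMapEmbedding(TransformerMixin, BaseEstimator):
    """Diffusion components of the cell-cell Markov matrix.

    Eigenvectors are computed through the symmetric conjugate
    D^{-1/2} A D^{-1/2} (real spectrum guaranteed) and converted back to
    right eigenvectors of the Markov matrix, each normalized to unit length.
    The trivial unit eigenvalue is dropped; the embedding dimension is the
    position of the largest eigen gap among the leading eigenvalues, capped
    at ``n_components`` (pass an int to force a dimension).
    """

    def __init__(self, k: int = 27, ka: int = 12, n_components="auto",
                 max_components: int = 10):
        self.k = k
        self.ka = ka
        self.n_components = n_components
        self.max_components = max_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < self.max_components + 2:
            raise ValueError("too few cells for the requested embedding")
        aff = adaptive_affinity(X, k=min(self.k, n - 1), ka=min(self.ka, min(self.k, n - 1)))
        A = aff.matrix
        ncomp, labels = connected_components(A, directed=False)
        if ncomp > 1:
            sizes = np.bincount(labels).tolist()
            raise ValueError(f"cell graph is disconnected (component sizes {sizes})")
        d = np.asarray(A.sum(axis=1)).ravel()
        Dm = sp.diags(1.0 / np.sqrt(d))
        S = (Dm @ A @ Dm).tocsr()
        n_eig = min(self.max_components + 1, n - 1)
        vals, vecs = eigsh(S, k=n_eig, which="LA")
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        # right eigenvectors of M = D^-1 A are D^-1/2 v
        phi = Dm @ vecs
        phi /= np.linalg.norm(phi, axis=0, keepdims=True)
        # drop the trivial stationary component (lambda = 1)
        vals, phi = vals[1:], phi[:, 1:]
        if self.n_components == "auto":
            gaps = vals[:-1] - vals[1:]
            L = int(np.argmax(gaps)) + 1
        else:
            L = int(self.n_components)
            if L > vals.size:
                raise ValueError("n_components exceeds computed spectrum")
        self.eigenvalues_ = vals[:L]
        self.embedding_ = phi[:, :L]
        self.all_eigenvalues_ = vals
        self.n_components_ = L
        return self

    def transform(self, X=None):
        return self.embedding_

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


@dataclass
class DiffusionMap:
    eigenvalues: np.ndarray
    components: np.ndarray  # cells x L, unit-normalized
    k: int
    ka: int

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def diffusion_map(pcs, k: int = 27, ka: int = 12, n_components="auto",
                  max_components: int = 10) -> DiffusionMap:
    est = DiffusionMapEmbedding(
        k=k, ka=ka, n_components=n_components, max_components=max_components
    ).fit(pcs)
    return DiffusionMap(
        eigenvalues=est.eigenvalues_, components=est.embedding_, k=est.k, ka=est.ka
    )


def _scaled_embedding(dm: DiffusionMap, mode: str = "multiscale", t: int = 1) -> np.ndarray:
    lam = dm.eigenvalues
    if np.any(lam >= 1.0):
        raise ValueError("retained eigenvalue equal to 1; drop the trivial component")
    if mode == "multiscale":
        w = lam / (1.0 - lam)
    elif mode == "single-t":
        w = lam**t
    else:
        raise ValueError("mode must be 'multiscale' or 'single-t'")
    return dm.components * w[None, :]


def multiscale_distance(dm: DiffusionMap, i: int, j: int,
                        mode: str = "multiscale", t: int = 1) -> float:
    """Diffusion distance between cells i and j:
    D^2 = sum_l w_l^2 (e_{l,i} - e_{l,j})^2 with w_l = lambda_l/(1-lambda_l)
    (multi-scale) or lambda_l^t (single diffusion time)."""
    E = _scaled_embedding(dm, mode=mode, t=t)
    return float(np.linalg.norm(E[i] - E[j]))


def multiscale_distances_to(dm: DiffusionMap, anchors, mode: str = "multiscale",
                            t: int = 1) -> np.ndarray:
    """Distances from every cell to each anchor cell (cells x anchors)."""
    E = _scaled_embedding(dm, mode=mode, t=t)
    A = E[np.asarray(anchors, int)]
    return np.sqrt(((E[:, None, :] - A[None, :, :]) ** 2).sum(axis=2))


# ---------------------------------------------------------------------------
# PCHA


def furthest_sum(X: np.ndarray, K: int, rng) -> np.ndarray:
    """Greedy max-sum-of-distances seeding of K data points (the classic
    PCHA initialization, with the first randomly chosen point re-picked)."""
    n = X.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    sumdist = np.linalg.norm(X - X[first], axis=1)
    while len(chosen) < K:
        cand = int(np.argmax(sumdist))
        if cand in chosen:  # ties on duplicate points
            mask = np.ones(n, bool)
            mask[chosen] = False
            if not mask.any():
                break
            cand = int(np.nonzero(mask)[0][np.argmax(sumdist[mask])])
        chosen.append(cand)
        sumdist += np.linalg.norm(X - X[cand], axis=1)
    # re-pick the seed point against the rest of the set
    if len(chosen) > 1:
        sumdist -= np.linalg.norm(X - X[first], axis=1)
        rest = chosen[1:]
        mask = np.ones(n, bool)
        mask[rest] = False
        repick = int(np.nonzero(mask)[0][np.argmax(sumdist[mask])])
        chosen = rest + [repick]
    return np.asarray(chosen[:K], dtype=int)


def _project_columns(M: np.ndarray, delta: float = 0.0) -> np.ndarray:
    """Clip negative entries and rescale each column sum into
    [1-delta, 1+delta] (exact simplex normalization when delta = 0)."""
    M = np.maximum(M, 0.0)
    s = M.sum(axis=0)
    dead = s <= 0
    if dead.any():
        M[:, dead] = 1.0 / M.shape[0]
        s = M.sum(axis=0)
    target = np.clip(s, 1.0 - delta, 1.0 + delta)
    return M * (target / s)[None, :]


class PCHA(TransformerMixin, BaseEstimator):
    """Principal convex hull (archetypal) analysis, X^T ~ X^T C S.

    Fitted attributes: ``archetypes_`` (K x d positions), ``C_`` (n x K
    convex weights defining archetypes over data points), ``S_`` (K x n
    stochastic weights reconstructing points), ``explained_variance_``,
    ``sse_history_`` (monotone non-increasing), ``converged_``.
    """

    def __init__(self, n_archetypes: int = 4, delta: float = 0.0,
                 max_iter: int = 400, tol: float = 1e-8, random_state: int = 0):
        self.n_archetypes = n_archetypes
        self.delta = delta
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- internal: one backtracking projected-gradient step ----------------
    # the raw gradient is first projected onto the tangent space of the
    # column simplex (subtract the S-weighted column mean), which keeps the
    # clip-and-renormalize projection from fighting the step direction
    @staticmethod
    def _step(M, grad, mu, project, sse_fn, sse_old, n_tries=40):
        grad = grad - (grad * M).sum(axis=0, keepdims=True)
        for _ in range(n_tries):
            M_new = project(M - mu * grad)
            sse_new = sse_fn(M_new)
            if sse_new <= sse_old:
                return M_new, sse_new, mu * 1.2
            mu /= 2.0
        return M, sse_old, mu

    def fit(self, X, y=None, init_C=None, init_S=None):
        Xn = np.asarray(X, dtype=float)  # n x d
        n, d = Xn.shape
        K = self.n_archetypes
        if not (1 <= K <= n):
            raise ValueError("need 1 <= n_archetypes <= n_points")
        rng = check_random_state(self.random_state)
        Xt = Xn.T  # d x n

        if init_C is not None:
            C = np.asarray(init_C, dtype=float).copy()
        else:
            seeds = furthest_sum(Xn, K, rng)
            C = np.zeros((n, K))
            C[seeds, np.arange(K)] = 1.0
        C = _project_columns(C, self.delta)

        A = Xt @ C  # d x K archetypes
        if init_S is not None:
            S = _project_columns(np.asarray(init_S, dtype=float).copy())
        else:
            # hard-assign each point to its nearest initial archetype
            dist = ((Xn[:, None, :] - A.T[None, :, :]) ** 2).sum(axis=2)
            S = np.zeros((K, n))
            S[np.argmin(dist, axis=1), np.arange(n)] = 1.0

        def sse(C=None, S_=None, A_=None):
            AA = Xt @ C if C is not None else A_
            R = AA @ (S_ if S_ is not None else S) - Xt
            return float((R**2).sum())

        sse_cur = sse(C=C, S_=S)
        history = [sse_cur]
        muC, muS = 1.0, 1.0
        converged = False
        for it in range(self.max_iter):
            A = Xt @ C
            # S step(s)
            for _ in range(3):
                R = A @ S - Xt
                grad_S = A.T @ R
                S, sse_cur, muS = self._step(
                    S, grad_S, muS, _project_columns,
                    lambda M: sse(A_=A, S_=M), sse_cur,
                )
            # C step
            R = (Xt @ C) @ S - Xt
            grad_C = Xt.T @ (R @ S.T)
            C, sse_cur, muC = self._step(
                C, grad_C, muC,
                lambda M: _project_columns(M, self.delta),
                lambda M: sse(C=M, S_=S), sse_cur,
            )
            history.append(sse_cur)
            prev = history[-2]
            if prev - sse_cur <= self.tol * max(prev, 1e-300):
                converged = True
                break
        if not converged:
            warnings.warn("PCHA did not converge within max_iter; returning best iterate")

        self.C_, self.S_ = C, S
        self.archetypes_ = (Xt @ C).T  # K x d
        sst = float(((Xn - Xn.mean(axis=0)) ** 2).sum())
        self.explained_variance_ = 1.0 - sse_cur / sst if sst > 0 else 1.0
        self.sse_history_ = np.asarray(history)
        self.n_iter_ = len(history) - 1
        self.converged_ = converged
        return self

    def transform(self, X):
        """Convex weights of (possibly new) points over the fitted
        archetypes, by projected gradient on S alone."""
        Xn = np.asarray(X, dtype=float)
        A = self.archetypes_.T  # d x K
        Xt = Xn.T
        K, n = A.shape[1], Xn.shape[0]
        dist = ((Xn[:, None, :] - self.archetypes_[None, :, :]) ** 2).sum(axis=2)
        S = np.zeros((K, n))
        S[np.argmin(dist, axis=1), np.arange(n)] = 1.0
        mu = 1.0
        sse_cur = float(((A @ S - Xt) ** 2).sum())
        for _ in range(200):
            grad = A.T @ (A @ S - Xt)
            S, sse_new, mu = self._step(
                S, grad, mu, _project_columns,
                lambda M: float(((A @ M - Xt) ** 2).sum()), sse_cur,
            )
            if sse_cur - sse_new <= 1e-10 * max(sse_cur, 1e-300):
                break
            sse_cur = sse_new
        return S.T


@dataclass
class ArchetypeModel:
    archetypes: np.ndarray  # K x d
    C: np.ndarray
    S: np.ndarray
    explained_variance: float
    delta: float
    seed: int
    n_iter: int
    converged: bool
    sse_history: np.ndarray = None


def pcha_fit(pcs, K: int, delta: float = 0.0, seed: int = 0,
             max_iter: int = 400, tol: float = 1e-8, **fit_kw) -> ArchetypeModel:
    est = PCHA(n_archetypes=K, delta=delta, max_iter=max_iter, tol=tol,
               random_state=seed).fit(pcs, **fit_kw)
    return ArchetypeModel(
        archetypes=est.archetypes_, C=est.C_, S=est.S_,
        explained_variance=est.explained_variance_, delta=delta, seed=seed,
        n_iter=est.n_iter_, converged=est.converged_, sse_history=est.sse_history_,
    )


def select_n_archetypes(
    pcs, K_grid, seed: int = 0, delta: float = 0.0, max_iter: int = 400,
    tol: float = 1e-8,
) -> tuple[int, np.ndarray, dict[int, ArchetypeModel]]:
    """Fit PCHA along an ascending K grid (warm-starting each K from the
    previous solution plus the worst-reconstructed point, which makes the
    explained-variance curve monotone) and return the knee-point K, the
    explained-variance curve, and the fitted models."""
    K_grid = [int(k) for k in sorted(K_grid)]
    X = np.asarray(pcs, dtype=float)
    models: dict[int, ArchetypeModel] = {}
    ev = []
    prev = None
    for K in K_grid:
        kw = {}
        if prev is not None and K == prev.C.shape[1] + 1:
            resid = np.linalg.norm(X - prev.S.T @ prev.archetypes, axis=1)
            extra = int(np.argmax(resid))
            C = np.hstack([prev.C, np.zeros((X.shape[0], 1))])
            C[extra, -1] = 1.0
            S = np.vstack([prev.S, np.zeros((1, X.shape[0]))])
            kw = {"init_C": C, "init_S": S}
        m = pcha_fit(X, K, delta=delta, seed=seed, max_iter=max_iter, tol=tol, **kw)
        models[K] = m
        ev.append(m.explained_variance)
        prev = m
    ev = np.asarray(ev)
    if len(K_grid) == 1:
        return K_grid[0], ev, models
    # the knee is located on log residual variance: raw explained variance
    # saturates at the true archetype count, and the log scale keeps the
    # early steep gains from masking that saturation point
    try:
        log_resid = np.log(np.maximum(1.0 - ev, 1e-12))
        chosen = K_grid[knee_point(log_resid, x=np.asarray(K_grid, float))]
    except FitError:
        warnings.warn("flat explained-variance curve: returning the smallest K")
        chosen = K_grid[0]
    return chosen, ev, models


# ---------------------------------------------------------------------------
# archetype neighborhoods


@dataclass
class ArchetypeNeighborhoods:
    anchor_indices: np.ndarray  # per archetype: index of nearest cell
    radii: np.ndarray
    members: list[np.ndarray]  # per archetype: member cell indices
    nearest_archetype: np.ndarray  # per cell


def archetype_neighborhoods(
    dm: DiffusionMap, model: ArchetypeModel, pcs, mode: str = "multiscale", t: int = 1
) -> ArchetypeNeighborhoods:
    """Anchor each archetype at its Euclidean-nearest cell in PC space, set
    its radius to half the multi-scale diffusion distance to the nearest
    other anchor, collect member cells within the radius, and assign every
    cell to its diffusion-nearest anchor."""
    X = np.asarray(pcs, dtype=float)
    K = model.archetypes.shape[0]
    d2 = ((X[:, None, :] - model.archetypes[None, :, :]) ** 2).sum(axis=2)
    anchors = np.argmin(d2, axis=0)
    if np.unique(anchors).size < K:
        raise ValueError("degenerate archetypes: two archetypes share an anchor cell")
    D = multiscale_distances_to(dm, anchors, mode=mode, t=t)  # cells x K
    anchor_D = D[anchors]  # K x K anchor-to-anchor distances
    radii = np.zeros(K)
    for a in range(K):
        others = np.delete(anchor_D[a], a)
        radii[a] = 0.5 * others.min()
    members = [np.nonzero(D[:, a] < radii[a])[0] for a in range(K)]
    nearest = np.argmin(D, axis=1)
    return ArchetypeNeighborhoods(
        anchor_indices=anchors, radii=radii, members=members, nearest_archetype=nearest
    )


# ---------------------------------------------------------------------------
# EMD marker scoring


def emd_score(sample_a, sample_b) -> float:
    """Earth mover's (1-D Wasserstein-1) distance between two empirical
    distributions with equal weights."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(wasserstein_distance(a, b))


def archetype_markers(
    imputed,
    nbhd: ArchetypeNeighborhoods,
    gene_mask=None,
    gene_ids=None,
    n_resamples: int = 100,
    seed: int = 0,
):
    """Mean EMD between each archetype neighborhood's expression and
    equal-sized background draws from non-member cells, per gene, averaged
    over ``n_resamples`` background draws.

    Because neighborhood and background always have the same size, the
    per-gene EMD reduces to the mean absolute difference of order
    statistics, which is computed vectorized across genes.
    """
    import pandas as pd

    values = imputed.values if hasattr(imputed, "values") and not isinstance(imputed, pd.DataFrame) else np.asarray(imputed)
    if gene_ids is None:
        gene_ids = getattr(imputed, "gene_ids", None)
    if gene_mask is not None:
        gene_mask = np.asarray(gene_mask, bool)
        values = values[:, gene_mask]
        if gene_ids is not None:
            gene_ids = [g for g, m in zip(gene_ids, gene_mask) if m]
    n, g = values.shape
    rng = check_random_state(seed)
    K = len(nbhd.members)
    scores = np.zeros((K, g))
    for a in range(K):
        mem = nbhd.members[a]
        if mem.size == 0:
            warnings.warn(f"archetype {a}: empty neighborhood, scores set to 0")
            continue
        comp = np.setdiff1d(np.arange(n), mem)
        replace = comp.size < mem.size
        if replace:
            warnings.warn(
                f"archetype {a}: neighborhood larger than its complement; "
                "sampling background with replacement"
            )
        fg = np.sort(values[mem], axis=0)  # size x genes, sorted per gene
        acc = np.zeros(g)
        for _ in range(n_resamples):
            bg = values[rng.choice(comp, size=mem.size, replace=replace)]
            acc += np.abs(fg - np.sort(bg, axis=0)).mean(axis=0)
        scores[a] = acc / n_resamples
    cols = gene_ids if gene_ids is not None else [f"g{i}" for i in range(g)]
    return pd.DataFrame(scores, index=[f"archetype_{a}" for a in range(K)], columns=cols)
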