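"""Graph community detection with ARI-based neighborhood-size selection and
reference-correlation cell-type annotation.

Cells are embedded in PC space, a k-NN graph is re-weighted by the Jaccard
overlap of neighbor sets, and communities are found by seeded modularity
optimization (Leiden). The neighborhood size k is chosen as the smallest k
whose partition is stable (ARI > 0.75 against larger k). Clusters are
annotated by Pearson correlation of centered cluster medians against a bulk
reference expression table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (permutation-model
    expectation correction)."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label arrays must have equal length")
    return float(adjusted_rand_score(a, b))


def jaccard_knn_graph(X, k: int) -> sp.csr_matrix:
    """k-NN graph with edges weighted by Jaccard overlap of neighbor sets."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    idx = idx[:, 1:]
    B = sp.csr_matrix(
        (np.ones(n * k), (np.repeat(np.arange(n), k), idx.ravel())), shape=(n, n)
    )
    union_edges = ((B + B.T) > 0).astype(float)
    inter = (B @ B.T).toarray() if n <= 2000 else None
    if inter is None:
        inter_sp = B @ B.T
        coo = union_edges.tocoo()
        ivals = np.asarray(inter_sp[coo.row, coo.col]).ravel()
    else:
        coo = union_edges.tocoo()
        ivals = inter[coo.row, coo.col]
    jac = ivals / (2.0 * k - ivals)
    W = sp.csr_matrix((jac, (coo.row, coo.col)), shape=(n, n))
    W.setdiag(0.0)
    W.eliminate_zeros()
    return W


@dataclass
class ClusterLabels:
    labels: np.ndarray
    k: int
    modularity: float


class GraphClustering(ClusterMixin, BaseEstimator):
    """Seeded modularity community detection on the Jaccard k-NN graph
    (sklearn clusterer: fit stores ``labels_``)."""

    def __init__(self, k: int = 35, random_state: int = 0):
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        W = jaccard_knn_graph(X, self.k)
        n = W.shape[0]
        coo = sp.triu(W, k=1).tocoo()
        g = ig.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
        if g.ecount() and not g.is_connected():
            sizes = sorted((len(c) for c in g.connected_components()), reverse=True)
            warnings.warn(f"Jaccard graph not fully connected (component sizes {sizes})")
        part = leidenalg.find_partition(
            g,
            leidenalg.ModularityVertexPartition,
            weights=coo.data.tolist(),
            seed=self.random_state,
        )
        labels = np.asarray(part.membership)
        # contiguous relabeling by first appearance for order stability
        _, labels = np.unique(labels, return_inverse=True)
        self.labels_ = labels
        self.modularity_ = float(part.quality())
        return self


def cluster_cells(pcs, k: int = 35, seed: int = 0) -> ClusterLabels:
    est = GraphClustering(k=k, random_state=seed).fit(pcs)
    return ClusterLabels(labels=est.labels_, k=k, modularity=est.modularity_)


@dataclass
class StabilityScan:
    k_grid: np.ndarray
    ari_matrix: np.ndarray
    chosen_k: int
    labels_by_k: dict[int, np.ndarray]


def stability_select_k(
    pcs, k_grid, stability_threshold: float = 0.75, seed: int = 0
) -> StabilityScan:
    """Cluster at every k in the grid and choose the minimum k whose median
    ARI against all larger k exceeds the threshold; fall back to max k with
    a warning when none qualifies."""
    k_grid = np.asarray(sorted(k_grid), dtype=int)
    if k_grid.size < 2:
        raise ValueError("k_grid must contain at least 2 values")
    labels = {int(k): cluster_cells(pcs, k=int(k), seed=seed).labels for k in k_grid}
    m = k_grid.size
    A = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            A[i, j] = A[j, i] = ari(labels[int(k_grid[i])], labels[int(k_grid[j])])
    chosen = None
    for i in range(m - 1):
        if np.median(A[i, i + 1 :]) > stability_threshold:
            chosen = int(k_grid[i])
            break
    if chosen is None:
        warnings.warn("no k reached the stability threshold; using the largest k")
        chosen = int(k_grid[-1])
    return StabilityScan(k_grid=k_grid, ari_matrix=A, chosen_k=chosen, labels_by_k=labels)


@dataclass
class AnnotationResult:
    correlations: pd.DataFrame  # clusters x reference cell types
    p_values: pd.DataFrame
    display_mask: pd.DataFrame  # |r| > r_min and p < p_max


def annotate_by_reference(
    labels,
    imputed,
    reference: pd.DataFrame,
    gene_ids=None,
    r_min: float = 0.2,
    p_max: float = 0.01,
) -> AnnotationResult:
    """Correlate centered cluster medians of imputed expression with a
    centered bulk reference (genes x cell types) over shared genes.

    p-values are the exact t-transform test for non-correlation with n-2 df.
    """
    labels = np.asarray(labels)
    values = imputed.values if hasattr(imputed, "values") and not isinstance(imputed, pd.DataFrame) else np.asarray(imputed)
    if gene_ids is None:
        gene_ids = getattr(imputed, "gene_ids", None)
    if gene_ids is None:
        raise ValueError("gene identifiers required to match the reference")
    shared = [g for g in gene_ids if g in set(reference.index)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes between matrix and reference")
    gi = {g: i for i, g in enumerate(gene_ids)}
    cols = [gi[g] for g in shared]

    uniq = np.unique(labels)
    medians = np.zeros((len(shared), uniq.size))
    for j, c in enumerate(uniq):
        members = labels == c
        if members.sum() == 1:
            warnings.warn(f"cluster {c} has a single cell; its median is that cell")
        medians[:, j] = np.median(values[members][:, cols], axis=0)
    medians -= medians.mean(axis=1, keepdims=True)  # center per gene across clusters

    ref = reference.loc[shared].to_numpy(dtype=float)
    ref = ref - ref.mean(axis=1, keepdims=True)

    nclu, nref = uniq.size, ref.shape[1]
    r = np.zeros((nclu, nref))
    p = np.ones((nclu, nref))
    for i in range(nclu):
        for j in range(nref):
            res = stats.pearsonr(medians[:, i], ref[:, j])
            r[i, j], p[i, j] = res.statistic, res.pvalue
    idx = [f"cluster_{c}" for c in uniq]
    rdf = pd.DataFrame(r, index=idx, columns=reference.columns)
    pdf = pd.DataFrame(p, index=idx, columns=reference.columns)
    mask = (rdf.abs() > r_min) & (pdf < p_max)
    return AnnotationResult(correlations=rdf, p_values=pdf, display_mask=mask)
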