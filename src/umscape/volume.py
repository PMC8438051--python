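"""Phenotypic volume: the log pseudo-determinant of the gene-gene covariance
matrix of a cell group, normalized by the number of genes.

log(volume) = sum over eigenvalues lambda_e > 0 of 0.5 * log10(lambda_e^2),
divided by the total gene count d. Eigenvalues come from the unbiased
(1/(n-1)) empirical covariance of the normalized but UN-imputed expression:
diffusion smoothing distorts gene-gene covariance, so it is never applied
here. Group comparisons subsample a fixed number of cells (default 150,
repeated 100 times) because the statistic grows with population size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import check_random_state


def log_phenotypic_volume(
    norm_expr, tol: float | None = None
) -> tuple[float, np.ndarray]:
    """Log10 pseudo-determinant of the covariance of ``norm_expr``
    (cells x genes), divided by the gene count.

    Eigenvalues are computed from the singular values of the centered data
    (lambda = s^2 / (n-1)), which never materializes the d x d covariance.
    ``tol`` defaults to max(lambda) * 1e-10; eigenvalues at or below it are
    treated as zero and dropped (their count is recoverable from the
    returned eigenvalue list).

    Returns (statistic, retained eigenvalues).
    """
    X = np.asarray(norm_expr, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    n, d = X.shape
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("zero covariance: all cells identical")
    s = np.linalg.svd(Xc, compute_uv=False)
    lam = s**2 / (n - 1)
    if tol is None:
        tol = lam.max() * 1e-10
    lam = lam[lam > tol]
    if lam.size == 0:
        raise ValueError("zero covariance: no eigenvalue above tolerance")
    stat = float(np.sum(0.5 * np.log10(lam**2)) / d)
    return stat, lam


@dataclass
class PhenotypicVolumeResult:
    volumes: np.ndarray  # one value per subsample
    eigenvalue_counts: np.ndarray
    n_cells: int
    n_repeats: int
    n_genes: int
    tol: float | None


def volume_distribution(
    norm_expr,
    cell_mask=None,
    n_cells: int = 150,
    n_repeats: int = 100,
    seed: int = 0,
    tol: float | None = None,
) -> PhenotypicVolumeResult:
    """Distribution of the volume statistic over repeated subsamples of a
    cell group (without replacement), controlling for group size."""
    X = np.asarray(norm_expr, dtype=float)
    if cell_mask is not None:
        X = X[np.asarray(cell_mask, bool)]
    if X.shape[0] < n_cells:
        raise ValueError(
            f"group has {X.shape[0]} cells but {n_cells} are required; the "
            "fixed subsample size is the cell-number control"
        )
    rng = check_random_state(seed)
    vols = np.zeros(n_repeats)
    counts = np.zeros(n_repeats, dtype=int)
    for r in range(n_repeats):
        # sorted draw: the statistic is row-order invariant, sorting makes
        # the identical-subset case bitwise reproducible
        draw = np.sort(rng.choice(X.shape[0], size=n_cells, replace=False))
        vols[r], lam = log_phenotypic_volume(X[draw], tol=tol)
        counts[r] = lam.size
    return PhenotypicVolumeResult(
        volumes=vols,
        eigenvalue_counts=counts,
        n_cells=n_cells,
        n_repeats=n_repeats,
        n_genes=X.shape[1],
        tol=tol,
    )
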