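"""Cell and gene quality control, median normalization, PCA with
library-size regression, and variable-gene selection.

Filters return boolean *retain* masks so the final kept set is the plain
conjunction of all masks, and a :class:`QCReport` records every cutoff for
audit. Viable cells are separated from ambient ("empty droplet") barcodes by
a knee rule on the empirical cumulative distribution of log library sizes;
apoptotic cells by a >25% mitochondrial-count fraction; low-complexity
libraries by a robust residual rule on genes-detected vs library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from ._utils import FitError, fit_bimodal, knee_point
from .io import CountMatrix


def _counts_array(counts) -> np.ndarray:
    if isinstance(counts, CountMatrix):
        return counts.to_dense()
    if sp.issparse(counts):
        return np.asarray(counts.todense(), dtype=float)
    return np.asarray(counts, dtype=float)


# ---------------------------------------------------------------------------
# cell filters


class KneeResult(NamedTuple):
    mask: np.ndarray  # True = retain
    cutoff: float  # in raw total-count units


def knee_filter_cells(counts, grid_size: int = 100, smooth_sigma: float = 2.0) -> KneeResult:
    """Separate cells from ambient barcodes at the knee of the smoothed ECDF
    of log10 total counts.

    The ECDF of log10(totals+1) is evaluated on a uniform grid and smoothed
    with a Gaussian kernel (sigma in grid steps). Between the ambient and
    cell modes of its derivative, the cutoff is placed where the ECDF slope
    is minimal — the sign change of the discrete second difference, i.e. the
    density valley separating the two barcode populations. Barcodes with
    totals strictly above the cutoff are retained. Unimodal or degenerate
    distributions retain everything with a warning.
    """
    totals = _counts_array(counts).sum(axis=1) if not _is_vector(counts) else np.asarray(counts, float)
    if np.unique(totals).size < 3:
        warnings.warn("fewer than 3 distinct library sizes: no knee, retaining all")
        return KneeResult(np.ones(totals.size, bool), -np.inf)

    logt = np.log10(totals + 1.0)
    grid = np.linspace(logt.min(), logt.max(), grid_size)
    ecdf = np.searchsorted(np.sort(logt), grid, side="right") / logt.size
    smooth = gaussian_filter1d(ecdf, smooth_sigma)
    density = np.gradient(smooth)
    peaks, props = find_peaks(density, prominence=0.05 * density.max())
    if peaks.size < 2:
        warnings.warn("library-size distribution unimodal: no knee, retaining all")
        return KneeResult(np.ones(totals.size, bool), -np.inf)

    # ambient mode = most prominent peak left of the rightmost (cell) mode
    cell_mode = peaks[-1]
    left = peaks[peaks < cell_mode]
    ambient_mode = left[np.argmax(props["prominences"][peaks < cell_mode])]
    window = slice(ambient_mode + 1, cell_mode)
    # two genuine barcode populations are separated by a deep density
    # valley; shallow shoulders of a unimodal distribution are not a knee
    if density[window].min() >= 0.5 * min(density[ambient_mode], density[cell_mode]):
        warnings.warn("library-size distribution effectively unimodal: no knee")
        return KneeResult(np.ones(totals.size, bool), -np.inf)
    cut_idx = ambient_mode + 1 + int(np.argmin(density[window]))
    cutoff = 10.0 ** grid[cut_idx] - 1.0
    return KneeResult(totals > cutoff, float(cutoff))


def _is_vector(x) -> bool:
    return not isinstance(x, CountMatrix) and not sp.issparse(x) and np.ndim(x) == 1


def complexity_filter(counts, n_mads: float = 3.0) -> np.ndarray:
    """Flag low-complexity libraries whose genes-detected falls far below the
    genes-vs-totals trend (OLS on log axes, residual < -n_mads robust SDs)."""
    arr = _counts_array(counts)
    if arr.shape[0] < 10:
        warnings.warn("fewer than 10 cells: complexity filter skipped")
        return np.ones(arr.shape[0], bool)
    totals = arr.sum(axis=1)
    detected = (arr > 0).sum(axis=1)
    x = np.log(totals + 1.0)
    y = np.log(detected + 1.0)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    mad = np.median(np.abs(resid - np.median(resid)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return np.ones(arr.shape[0], bool)
    return resid >= -n_mads * robust_sd


def mito_filter(counts: CountMatrix, max_fraction: float = 0.25) -> np.ndarray:
    """Retain cells with mitochondrial count fraction <= max_fraction
    (cells strictly above are considered apoptotic)."""
    if not counts.mito_mask.any():
        warnings.warn("no mitochondrial genes present: mito filter retains all")
        return np.ones(counts.n_cells, bool)
    arr = counts.counts
    totals = np.asarray(arr.sum(axis=1)).ravel()
    mito = np.asarray(arr[:, counts.mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return frac <= max_fraction


# ---------------------------------------------------------------------------
# gene filter


class GeneFilterResult(NamedTuple):
    mask: np.ndarray  # True = retain
    detection_counts: np.ndarray
    low_expression_cutoff: float  # log10 total-count scale; -inf if fit failed


def gene_filter(counts, min_cells: int = 10, n_sds: float = 5.0) -> GeneFilterResult:
    """Remove genes detected in fewer than ``min_cells`` cells, plus
    low-expression genes whose log10 total counts fall more than ``n_sds``
    standard deviations below the second (larger) mode of a two-component
    fit to the per-gene log-total distribution."""
    arr = _counts_array(counts)
    detection = (arr > 0).sum(axis=0)
    mask = detection >= min_cells
    totals = arr.sum(axis=0)
    cutoff = -np.inf
    pos = totals > 0
    try:
        logt = np.log10(totals[pos])
        (_, _), (mu2, sd2) = fit_bimodal(logt)
        cutoff = mu2 - n_sds * sd2
        low = np.ones(arr.shape[1], bool)
        low[pos] = logt >= cutoff
        low[~pos] = False
        mask = mask & low
    except FitError as exc:
        warnings.warn(f"bimodal gene-expression fit failed ({exc}); "
                      "applying detection rule only")
    return GeneFilterResult(mask, detection, float(cutoff))


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizedMatrix:
    """Median-library-size scaled expression; rows all sum to the median."""

    values: np.ndarray
    scale_factors: np.ndarray
    median_libsize: float
    cell_ids: list[str] | None = None
    gene_ids: list[str] | None = None


class MedianNormalizer(TransformerMixin, BaseEstimator):
    """Divide each cell by its total molecule count and rescale by the median
    total of the fitted cells (sklearn transformer)."""

    def fit(self, X, y=None):
        X = _counts_array(X)
        totals = X.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("zero-total cell encountered; filter cells first")
        self.median_libsize_ = float(np.median(totals))
        return self

    def transform(self, X):
        X = _counts_array(X)
        totals = X.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("zero-total cell encountered; filter cells first")
        return X / totals[:, None] * self.median_libsize_


def median_normalize(counts) -> NormalizedMatrix:
    cell_ids = counts.cell_ids if isinstance(counts, CountMatrix) else None
    gene_ids = counts.gene_ids if isinstance(counts, CountMatrix) else None
    X = _counts_array(counts)
    norm = MedianNormalizer()
    values = norm.fit_transform(X)
    totals = X.sum(axis=1)
    return NormalizedMatrix(
        values=values,
        scale_factors=norm.median_libsize_ / totals,
        median_libsize=norm.median_libsize_,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
    )


# ---------------------------------------------------------------------------
# PCA with library-size regression


@dataclass
class PCSpace:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    n_pcs: int


class LibsizeRegressedPCA(TransformerMixin, BaseEstimator):
    """Randomized PCA whose fitted scores have library size regressed out of
    every component by OLS (the explained-variance ratios are recorded
    before regression).

    ``fit_transform(X, library_size=...)`` returns the residualized scores
    for the fitted cells; ``transform`` on new data projects without
    regression.
    """

    def __init__(self, n_components: int = 50, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None, library_size=None):
        self.fit_transform(X, library_size=library_size)
        return self

    def fit_transform(self, X, y=None, library_size=None):
        X = np.asarray(X, dtype=float)
        n_max = min(X.shape)
        n = self.n_components
        if n > n_max:
            warnings.warn(f"n_components={n} exceeds matrix rank bound; using {n_max}")
            n = n_max
        self._pca = PCA(
            n_components=n, svd_solver="randomized", random_state=self.random_state
        )
        scores = self._pca.fit_transform(X)
        self.components_ = self._pca.components_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        if library_size is None:
            library_size = X.sum(axis=1)
        lib = np.asarray(library_size, dtype=float)
        D = np.column_stack([np.ones_like(lib), lib])
        beta, *_ = np.linalg.lstsq(D, scores, rcond=None)
        self.scores_ = scores - D @ beta
        return self.scores_

    def transform(self, X):
        return self._pca.transform(np.asarray(X, dtype=float))


def pca_libsize_regressed(norm, library_size=None, n_pcs: int = 50, seed: int = 0) -> PCSpace:
    values = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm, float)
    est = LibsizeRegressedPCA(n_components=n_pcs, random_state=seed)
    scores = est.fit_transform(values, library_size=library_size)
    return PCSpace(
        scores=scores,
        loadings=est.components_,
        explained_variance_ratio=est.explained_variance_ratio_,
        n_pcs=scores.shape[1],
    )


class PCSelection(NamedTuple):
    n_knee: int
    n_target: int


def select_n_pcs(explained_variance_ratios, target_fraction: float = 0.90) -> PCSelection:
    """Number of PCs at the knee of cumulative explained variance
    (max-distance-to-chord), plus the smallest number reaching
    ``target_fraction`` of variance. Falls back to the target rule when the
    chord rule is undefined."""
    evr = np.asarray(explained_variance_ratios, dtype=float)
    cum = np.cumsum(evr)
    n_target = min(int(np.searchsorted(cum, target_fraction - 1e-9) + 1), evr.size)
    if evr.size < 3:
        return PCSelection(evr.size, evr.size)
    try:
        # prepend the origin (0 PCs explain 0 variance) so a dominant first
        # component registers as a knee at n = 1
        n_knee = max(knee_point(np.concatenate([[0.0], cum])), 1)
    except FitError:
        warnings.warn("cumulative variance curve flat: falling back to target rule")
        n_knee = n_target
    # a uniform spectrum has no curvature: the chord rule then returns an
    # arbitrary interior point; detect and fall back
    if np.allclose(evr, evr[0], rtol=1e-9, atol=1e-12):
        warnings.warn("uniform variance ratios: knee undefined, using target rule")
        n_knee = n_target
    return PCSelection(int(n_knee), int(n_target))


# ---------------------------------------------------------------------------
# variable genes


def variable_genes(norm, n_sds: float = 1.5) -> np.ndarray:
    """Select variably expressed genes: per-gene SD above mu2 - n_sds*sd2 of
    the larger-mean component of a two-Gaussian fit to the SD distribution.
    Falls back to the top SD quartile when the fit degenerates."""
    values = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm, float)
    if values.shape[0] < 2:
        raise ValueError("need >= 2 cells to estimate gene variability")
    sds = values.std(axis=0, ddof=1)
    try:
        (_, _), (mu2, sd2) = fit_bimodal(sds)
        threshold = mu2 - n_sds * sd2
    except FitError as exc:
        warnings.warn(f"variable-gene bimodal fit failed ({exc}); using top quartile")
        threshold = np.quantile(sds, 0.75)
    return (sds > threshold) & (sds > 0)


# ---------------------------------------------------------------------------
# report


@dataclass
class QCReport:
    """Per-barcode metrics, per-filter masks and recorded cutoffs."""

    total_counts: np.ndarray
    genes_detected: np.ndarray
    mito_fraction: np.ndarray
    cell_masks: dict[str, np.ndarray] = field(default_factory=dict)
    gene_masks: dict[str, np.ndarray] = field(default_factory=dict)
    knee_cutoff: float = np.nan
    gene_expression_cutoff: float = np.nan
    gene_detection_counts: np.ndarray | None = None

    @property
    def cell_mask(self) -> np.ndarray:
        out = np.ones(self.total_counts.size, bool)
        for m in self.cell_masks.values():
            out &= m
        return out

    @property
    def gene_mask(self) -> np.ndarray:
        masks = list(self.gene_masks.values())
        out = masks[0].copy()
        for m in masks[1:]:
            out &= m
        return out

    def reconcile(self) -> dict[str, int]:
        """Inclusion-exclusion audit of retained vs excluded barcodes."""
        n = self.total_counts.size
        excluded_any = ~self.cell_mask
        uniquely = {}
        for name, m in self.cell_masks.items():
            others = np.ones(n, bool)
            for other_name, om in self.cell_masks.items():
                if other_name != name:
                    others &= om
            uniquely[name] = int(np.sum(~m & others))
        overlap = int(excluded_any.sum() - sum(uniquely.values()))
        return {
            "total": n,
            "retained": int(self.cell_mask.sum()),
            "excluded": int(excluded_any.sum()),
            **{f"only_{k}": v for k, v in uniquely.items()},
            "multi_filter_overlap": overlap,
        }


def run_qc(
    counts: CountMatrix,
    min_cells_per_gene: int = 10,
    mito_max: float = 0.25,
    apply_complexity: bool = True,
) -> tuple[CountMatrix, QCReport]:
    """Run all cell filters, then gene filters on the retained cells, and
    return the filtered matrix plus a full report."""
    arr_totals = counts.library_sizes()
    detected = np.asarray((counts.counts > 0).sum(axis=1)).ravel()
    mito = (
        np.asarray(counts.counts[:, counts.mito_mask].sum(axis=1)).ravel()
        if counts.mito_mask.any()
        else np.zeros(counts.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(arr_totals > 0, mito / np.maximum(arr_totals, 1), 0.0)

    knee = knee_filter_cells(arr_totals)
    masks = {"knee": knee.mask, "mito": mito_filter(counts, mito_max)}
    if apply_complexity:
        masks["complexity"] = complexity_filter(counts)

    report = QCReport(
        total_counts=arr_totals,
        genes_detected=detected,
        mito_fraction=mito_frac,
        cell_masks=masks,
        knee_cutoff=knee.cutoff,
    )
    kept = counts.subset(cell_mask=report.cell_mask)
    gf = gene_filter(kept, min_cells=min_cells_per_gene)
    report.gene_masks["detection_and_expression"] = gf.mask
    report.gene_detection_counts = gf.detection_counts
    report.gene_expression_cutoff = gf.low_expression_cutoff
    return kept.subset(gene_mask=gf.mask), report
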