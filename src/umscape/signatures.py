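"""Per-cell signature scoring, Bayesian Gaussian mixture prognostic
classification, bootstrap class-fraction estimation, and ranked-cell
moving-average matrices.

Cells are scored by the mean imputed expression of each signature's genes;
a variational Bayesian GMM over the score space assigns each cell a
prognostic class (two components with diagonal covariance for the GEP1/GEP2
split; four components with spherical — or tied — covariance for the
TCGA-like subtypes). Per-patient class fractions are corrected for unequal
cell numbers by repeated fixed-size subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import BayesianGaussianMixture

from ._utils import check_random_state
from .io import GeneSignatureSet, restrict_signatures

_COV_MAP = {"diagonal": "diag", "spherical": "spherical", "tied": "tied"}


def score_signature(imputed, sigs: GeneSignatureSet, gene_ids=None) -> pd.DataFrame:
    """Per-cell unweighted mean expression of each signature's genes
    (one column per signature); absent genes are dropped with a warning."""
    values = imputed.values if hasattr(imputed, "values") and not isinstance(imputed, pd.DataFrame) else np.asarray(imputed)
    if gene_ids is None:
        gene_ids = getattr(imputed, "gene_ids", None)
    if gene_ids is None:
        raise ValueError("gene identifiers required for signature scoring")
    sigs = restrict_signatures(sigs, list(gene_ids))
    gi = {g: i for i, g in enumerate(gene_ids)}
    out = {}
    for name, genes in sigs.signatures.items():
        cols = [gi[g] for g in genes]
        out[name] = values[:, cols].mean(axis=1)
    index = getattr(imputed, "cell_ids", None)
    return pd.DataFrame(out, index=index)


class SignatureClassifier(BaseEstimator):
    """Variational Bayesian GMM over signature-score space (sklearn
    estimator: fit / predict / predict_proba).

    Components are relabeled after fitting by ascending mean along
    ``order_axis`` (default: the last score column, i.e. the
    aggressive-signature axis), so label ``n_components - 1`` is always the
    class highest on that axis. k-means initialization with a fixed seed
    makes fits reproducible; the weight-concentration prior is
    1/n_components.
    """

    def __init__(
        self,
        n_components: int = 2,
        covariance: str = "diagonal",
        order_axis: int = -1,
        random_state: int = 0,
        max_iter: int = 500,
    ):
        self.n_components = n_components
        self.covariance = covariance
        self.order_axis = order_axis
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] < self.n_components:
            raise ValueError("fewer cells than mixture components")
        if np.allclose(X, X[0], atol=1e-12):
            raise ValueError("no separable structure: all scores identical")
        if self.covariance not in _COV_MAP:
            raise ValueError(f"covariance must be one of {sorted(_COV_MAP)}")
        self._bgmm = BayesianGaussianMixture(
            n_components=self.n_components,
            covariance_type=_COV_MAP[self.covariance],
            weight_concentration_prior_type="dirichlet_distribution",
            weight_concentration_prior=1.0 / self.n_components,
            init_params="kmeans",
            max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(X)
        order = np.argsort(self._bgmm.means_[:, self.order_axis])
        self._order = order
        self.means_ = self._bgmm.means_[order]
        self.weights_ = self._bgmm.weights_[order]
        self.labels_ = self.predict(X)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._bgmm.predict_proba(X)[:, self._order]

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


@dataclass
class MixtureAssignment:
    labels: np.ndarray
    posteriors: np.ndarray
    means: np.ndarray
    n_components: int
    covariance: str
    seed: int


def fit_bgmm(
    scores,
    n_components: int = 2,
    covariance: str = "diagonal",
    order_axis: int = -1,
    seed: int = 0,
) -> MixtureAssignment:
    """Fit the BGMM classifier to a score matrix and return per-cell labels
    and posterior probabilities."""
    X = scores.to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    est = SignatureClassifier(
        n_components=n_components,
        covariance=covariance,
        order_axis=order_axis,
        random_state=seed,
    ).fit(X)
    return MixtureAssignment(
        labels=est.labels_,
        posteriors=est.predict_proba(X),
        means=est.means_,
        n_components=n_components,
        covariance=covariance,
        seed=seed,
    )


@dataclass
class FractionEstimate:
    """Per-patient class-fraction means and percentile 95% CIs across
    fixed-size resampling rounds."""

    table: pd.DataFrame  # patient x (class, stat) wide table
    n_rounds: int
    n_cells_per_round: int

    def mean(self, patient: str, cls: int) -> float:
        return float(self.table.loc[patient, f"class{cls}_mean"])

    def ci(self, patient: str, cls: int) -> tuple[float, float]:
        return (
            float(self.table.loc[patient, f"class{cls}_lo"]),
            float(self.table.loc[patient, f"class{cls}_hi"]),
        )


def bootstrap_fractions(
    labels,
    patient_ids,
    n_classes: int | None = None,
    n_cells: int = 500,
    n_rounds: int = 20,
    seed: int = 0,
) -> FractionEstimate:
    """Per patient: class fractions over ``n_rounds`` draws of ``n_cells``
    cells (without replacement when enough cells are available, with
    replacement otherwise so the draw size stays fixed); mean and 2.5/97.5
    percentile bounds across rounds."""
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    if labels.shape != patient_ids.shape:
        raise ValueError("labels and patient_ids must align")
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    rng = check_random_state(seed)
    rows = {}
    for patient in pd.unique(patient_ids):
        idx = np.nonzero(patient_ids == patient)[0]
        if idx.size == 0:
            raise ValueError(f"unknown patient id: {patient}")
        replace = idx.size < n_cells
        if replace:
            warnings.warn(
                f"patient {patient}: {idx.size} cells < draw size {n_cells}; "
                "sampling with replacement"
            )
        fracs = np.zeros((n_rounds, n_classes))
        for r in range(n_rounds):
            draw = rng.choice(idx, size=n_cells, replace=replace)
            counts = np.bincount(labels[draw], minlength=n_classes)
            fracs[r] = counts / n_cells
        row = {}
        for c in range(n_classes):
            row[f"class{c}_mean"] = fracs[:, c].mean()
            row[f"class{c}_lo"] = np.percentile(fracs[:, c], 2.5)
            row[f"class{c}_hi"] = np.percentile(fracs[:, c], 97.5)
        rows[patient] = row
    return FractionEstimate(
        table=pd.DataFrame(rows).T, n_rounds=n_rounds, n_cells_per_round=n_cells
    )


@dataclass
class RankedMatrix:
    values: np.ndarray  # genes x ranked cells, smoothed z-scores
    gene_ids: list[str]
    cell_order: np.ndarray
    ranking_signature: str
    window: int


def ranked_matrix(
    imputed,
    scores: pd.DataFrame,
    rank_sig: str,
    display_genes,
    gene_ids=None,
    window: int = 20,
) -> RankedMatrix:
    """Genes x cells matrix for ranked heatmaps: cells sorted ascending by a
    signature score, genes z-normalized across all cells, then smoothed with
    a centered moving average (shrunken windows at the edges)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    values = imputed.values if hasattr(imputed, "values") and not isinstance(imputed, pd.DataFrame) else np.asarray(imputed)
    if gene_ids is None:
        gene_ids = getattr(imputed, "gene_ids", None)
    if gene_ids is None:
        raise ValueError("gene identifiers required")
    if window > values.shape[0]:
        raise ValueError("window larger than the number of cells")
    gi = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in display_genes if g not in gi]
    if missing:
        raise ValueError(f"display genes absent from matrix: {missing}")

    order = np.argsort(scores[rank_sig].to_numpy(), kind="stable")
    sub = values[:, [gi[g] for g in display_genes]]
    mu, sd = sub.mean(axis=0), sub.std(axis=0)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn("constant display gene(s): z-scores set to zero")
        sd = np.where(zero_sd, 1.0, sd)
    z = (sub - mu) / sd
    z[:, zero_sd] = 0.0
    z = z[order]  # cells ranked ascending
    smoothed = (
        pd.DataFrame(z)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return RankedMatrix(
        values=smoothed.T,
        gene_ids=list(display_genes),
        cell_order=order,
        ranking_signature=rank_sig,
        window=window,
    )
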