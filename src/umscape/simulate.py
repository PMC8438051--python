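"""Synthetic droplet scRNA-seq atlases with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:
tumor cells whose expression rates are convex combinations of K archetypal
programs (Dirichlet weights), minority non-tumor cells with their own marker
block, lognormal library sizes, Poisson (optionally negative-binomial)
molecule counts, a mitochondrial gene subset with a Beta-distributed count
fraction (plus a designated apoptotic subpopulation above the 25% rule), and
ambient "empty droplet" barcodes drawn from the mean cell profile at a small
fraction of a typical library size.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import check_random_state
from .io import CountMatrix, GeneSignatureSet


@dataclass
class SimulationParams:
    """Study-scale defaults: ~2000-count cells, ~50-count ambient barcodes."""

    n_tumor_cells: int = 1000
    n_empty_droplets: int = 10000
    n_other_cells: int = 100
    n_genes: int = 300  # non-mitochondrial genes
    n_mito_genes: int = 10
    n_archetypes: int = 3
    archetype_programs: np.ndarray | None = None  # K x n_genes rates
    dirichlet_alpha: float = 0.5
    libsize_logmean: float = float(np.log(2000.0))
    libsize_logsd: float = 0.35
    empty_libsize_scale: float = 0.025
    mito_fraction_mean: float = 0.05
    mito_concentration: float = 200.0
    apoptotic_fraction: float = 0.02
    apoptotic_mito_mean: float = 0.40
    nb_dispersion: float | None = None  # NB size parameter; None = Poisson
    n_patients: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_archetypes < 2:
            raise ValueError("K >= 2 archetypal programs required")
        if not (0.0 < self.empty_libsize_scale < 1.0):
            raise ValueError("empty_libsize_scale must lie in (0, 1)")
        if not (0.0 <= self.mito_fraction_mean <= 1.0):
            raise ValueError("mito_fraction_mean must lie in [0, 1]")
        if self.archetype_programs is not None:
            progs = np.asarray(self.archetype_programs, dtype=float)
            if progs.shape != (self.n_archetypes, self.n_genes):
                raise ValueError("archetype_programs must be K x n_genes")
            if np.any(progs < 0):
                raise ValueError("program rates must be non-negative")
            self.archetype_programs = progs


def default_programs(K: int, n_genes: int, base: float = 1.0, boost: float = 6.0) -> np.ndarray:
    """K programs sharing a flat baseline, each boosting its own gene block."""
    progs = np.full((K, n_genes), base)
    block = max(1, n_genes // (2 * (K + 1)))
    for k in range(K):
        progs[k, k * block : (k + 1) * block] = boost
    return progs


def _gene_ids(n_genes: int, n_mito: int) -> tuple[list[str], np.ndarray]:
    ids = [f"GENE{i:04d}" for i in range(n_genes)] + [f"MT-{i}" for i in range(n_mito)]
    mito = np.zeros(n_genes + n_mito, bool)
    mito[n_genes:] = True
    return ids, mito


def _sample_counts(rng, mean, nb_dispersion=None):
    if nb_dispersion is None:
        return rng.poisson(mean)
    # NB as Gamma-Poisson mixture with size (shape) parameter r
    r = nb_dispersion
    lam = rng.gamma(shape=r, scale=mean / r, size=mean.shape)
    return rng.poisson(lam)


def simulate_atlas(params: SimulationParams) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a droplet atlas: tumor cells on an archetypal continuum,
    minority non-tumor cells, apoptotic cells and ambient empty droplets.

    Returns the CountMatrix plus a ground-truth table (one row per barcode)
    with patient, type label, class label, archetype weights, library-size
    factor and mitochondrial fraction.
    """
    rng = check_random_state(params.seed)
    K, G, M = params.n_archetypes, params.n_genes, params.n_mito_genes
    gene_ids, mito_mask = _gene_ids(G, M)

    progs = params.archetype_programs
    if progs is None:
        progs = default_programs(K, G)

    rows = []
    profiles = []  # per real cell: rate vector over non-mito genes, sums to 1
    weights_list = []

    # tumor cells: convex combinations of archetype programs
    n_t = params.n_tumor_cells
    w = rng.dirichlet(np.full(K, params.dirichlet_alpha), size=n_t) if n_t else np.zeros((0, K))
    tumor_rates = w @ progs
    for i in range(n_t):
        rate = tumor_rates[i]
        profiles.append(rate / rate.sum())
        weights_list.append(w[i])
        rows.append(
            {
                "patient": f"P{(i % params.n_patients) + 1}",
                "cell_type": "tumor",
                "class_label": f"archetype-{int(np.argmax(w[i]))}",
            }
        )

    # non-tumor cells: flat baseline boosted on the final gene block
    other_prog = np.full(G, 1.0)
    block = max(1, G // (2 * (K + 1)))
    other_prog[G - block :] = 8.0
    for i in range(params.n_other_cells):
        profiles.append(other_prog / other_prog.sum())
        weights_list.append(np.full(K, np.nan))
        rows.append({"patient": f"P{(i % params.n_patients) + 1}",
                     "cell_type": "other", "class_label": "other"})

    n_real = len(profiles)
    profiles = np.asarray(profiles) if n_real else np.zeros((0, G))

    # mitochondrial fraction per real cell; leading tumor cells can be
    # designated apoptotic (high-mito) for threshold tests
    n_apopt = int(round(params.apoptotic_fraction * n_t))
    mito_mean = np.full(n_real, params.mito_fraction_mean)
    mito_mean[:n_apopt] = params.apoptotic_mito_mean
    if params.mito_fraction_mean == 0 and n_apopt == 0:
        mito_frac = np.zeros(n_real)
    else:
        c = params.mito_concentration
        a = np.clip(mito_mean * c, 1e-6, None)
        b = np.clip((1.0 - mito_mean) * c, 1e-6, None)
        mito_frac = np.where(mito_mean > 0, rng.beta(a, b), 0.0)

    mito_profile = np.full(M, 1.0 / M) if M else np.zeros(0)
    full_profiles = np.hstack(
        [
            profiles * (1.0 - mito_frac[:, None]),
            mito_frac[:, None] * mito_profile[None, :],
        ]
    )

    libsizes = rng.lognormal(params.libsize_logmean, params.libsize_logsd, size=n_real)
    real_counts = _sample_counts(rng, libsizes[:, None] * full_profiles, params.nb_dispersion)

    # empty droplets: ambient profile = mean cell profile, tiny library size
    n_e = params.n_empty_droplets
    if n_e:
        ambient = full_profiles.mean(axis=0) if n_real else np.full(G + M, 1.0 / (G + M))
        ambient = ambient / ambient.sum()
        empty_lib = params.empty_libsize_scale * rng.lognormal(
            params.libsize_logmean, params.libsize_logsd, size=n_e
        )
        empty_counts = _sample_counts(rng, empty_lib[:, None] * ambient[None, :])
    else:
        empty_counts = np.zeros((0, G + M), dtype=int)
        empty_lib = np.zeros(0)

    for i in range(n_e):
        rows.append({"patient": "ambient", "cell_type": "empty", "class_label": "empty"})
        weights_list.append(np.full(K, np.nan))

    counts = np.vstack([real_counts, empty_counts]).astype(np.int64)
    barcodes = [f"BC{i:06d}" for i in range(counts.shape[0])]
    cm = CountMatrix(
        counts=sp.csr_matrix(counts), cell_ids=barcodes, gene_ids=gene_ids, mito_mask=mito_mask
    )

    truth = pd.DataFrame(rows, index=barcodes)
    truth["libsize_factor"] = np.concatenate([libsizes, empty_lib])
    truth["mito_fraction"] = np.concatenate([mito_frac, np.zeros(n_e)])
    truth["apoptotic"] = False
    truth.iloc[:n_apopt, truth.columns.get_loc("apoptotic")] = True
    wmat = np.asarray(weights_list) if weights_list else np.zeros((0, K))
    for k in range(K):
        truth[f"archetype_w{k}"] = wmat[:, k]
    return cm, truth


# ---------------------------------------------------------------------------
# two-class (GEP1-like vs GEP2-like) generator


@dataclass
class TwoClassParams:
    """Conditions for the prognostic-class generator: 2000 cells per patient,
    12-gene signatures, per-gene lognormal biological noise."""

    n_cells_per_patient: int = 2000
    n_signature_genes: int = 12
    n_background_genes: int = 200
    gene_noise_sd: float = 0.5  # sd of per-cell lognormal rate noise
    signature_base_weight: float = 3.0
    libsize_logmean: float = float(np.log(2000.0))
    libsize_logsd: float = 0.35
    seed: int = 0


def two_class_signatures(n_signature_genes: int = 12) -> GeneSignatureSet:
    """Gene lists matching the two-class generator's signature blocks."""
    return GeneSignatureSet(
        {
            "GEP1": [f"GEP1_{i:02d}" for i in range(n_signature_genes)],
            "GEP2": [f"GEP2_{i:02d}" for i in range(n_signature_genes)],
        }
    )


def simulate_two_class(
    fracs: dict[str, float], separation: float, params: TwoClassParams | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Cells from two transcriptional classes over-expressing their own
    signature block.

    ``fracs`` maps patient id -> expected fraction of GEP2-like cells.
    ``separation`` is the per-gene effect size: each class shifts the
    log-rate of its own signature genes by ``separation x gene_noise_sd``.
    separation 0 makes the classes indistinguishable.
    """
    if params is None:
        params = TwoClassParams()
    if separation < 0:
        raise ValueError("separation must be >= 0")
    for p, f in fracs.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"class fraction for {p} outside [0, 1]")

    rng = check_random_state(params.seed)
    ns = params.n_signature_genes
    gene_ids = (
        [f"GEP1_{i:02d}" for i in range(ns)]
        + [f"GEP2_{i:02d}" for i in range(ns)]
        + [f"BG{i:04d}" for i in range(params.n_background_genes)]
    )
    G = len(gene_ids)
    base_log = np.log(
        np.concatenate(
            [
                np.full(2 * ns, params.signature_base_weight),
                np.full(params.n_background_genes, 1.0),
            ]
        )
    )

    all_counts, rows = [], []
    sd = params.gene_noise_sd
    for patient, f2 in fracs.items():
        n = params.n_cells_per_patient
        is_gep2 = rng.random(n) < f2
        logrates = base_log[None, :] + rng.normal(0.0, sd, size=(n, G))
        shift = separation * sd
        logrates[~is_gep2, :ns] += shift  # GEP1-like boost own block
        logrates[is_gep2, ns : 2 * ns] += shift
        rates = np.exp(logrates)
        profiles = rates / rates.sum(axis=1, keepdims=True)
        libsizes = rng.lognormal(params.libsize_logmean, params.libsize_logsd, size=n)
        all_counts.append(rng.poisson(libsizes[:, None] * profiles))
        for i in range(n):
            rows.append(
                {
                    "patient": patient,
                    "cell_type": "tumor",
                    "class_label": "GEP2" if is_gep2[i] else "GEP1",
                    "libsize_factor": libsizes[i],
                }
            )

    counts = np.vstack(all_counts).astype(np.int64)
    barcodes = [f"TC{i:06d}" for i in range(counts.shape[0])]
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=barcodes,
        gene_ids=gene_ids,
        mito_mask=np.zeros(G, bool),
    )
    return cm, pd.DataFrame(rows, index=barcodes)


# ---------------------------------------------------------------------------
# simplex fixture for archetypal analysis


def simulate_simplex(
    K: int,
    n_points: int,
    noise_sd: float,
    dim: int,
    seed: int = 0,
    dirichlet_alpha: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Points drawn as Dirichlet convex combinations of K planted vertices
    plus isotropic Gaussian noise. Returns (points n x dim, vertices K x dim)."""
    if K > n_points:
        raise ValueError("need at least K points")
    if dim < K - 1:
        warnings.warn("dim < K - 1: the planted simplex is degenerate")
    rng = check_random_state(seed)
    vertices = rng.normal(0.0, 5.0, size=(K, dim))
    weights = rng.dirichlet(np.full(K, dirichlet_alpha), size=n_points)
    points = weights @ vertices
    if noise_sd > 0:
        points = points + rng.normal(0.0, noise_sd, size=points.shape)
    return points, vertices
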