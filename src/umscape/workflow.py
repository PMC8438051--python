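"""End-to-end analysis: QC -> normalization -> imputation -> prognostic
classification -> phenotypic volume -> diffusion geometry -> archetypes ->
marker scoring, driven by a single seeded RunConfig."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    archetype_markers,
    archetype_neighborhoods,
    diffusion_map,
    select_n_archetypes,
)
from .imputation import impute
from .io import CountMatrix, GeneSignatureSet, RunConfig
from .qc import (
    QCReport,
    median_normalize,
    pca_libsize_regressed,
    run_qc,
    select_n_pcs,
    variable_genes,
)
from .signatures import bootstrap_fractions, fit_bgmm, score_signature
from .volume import volume_distribution


@dataclass
class AnalysisResult:
    qc_report: QCReport
    filtered: CountMatrix
    variable_gene_mask: np.ndarray
    signature_scores: pd.DataFrame | None = None
    assignment: object = None
    fractions: object = None
    volumes: dict = field(default_factory=dict)
    n_archetypes: int | None = None
    archetype_model: object = None
    neighborhoods: object = None
    marker_table: pd.DataFrame | None = None


def analyze(
    counts: CountMatrix,
    sigs: GeneSignatureSet | None,
    config: RunConfig | None = None,
    patient_ids=None,
    archetype_k_grid=range(2, 7),
) -> AnalysisResult:
    """Run the full pipeline on a count matrix.

    ``patient_ids`` (aligned with ``counts.cell_ids``) enables per-patient
    class-fraction bootstrapping; ``sigs`` provides the prognostic
    signatures scored for the mixture model (the last signature is treated
    as the aggressive axis). All stochastic stages derive their seeds from
    ``config.seed``.
    """
    if config is None:
        config = RunConfig()
    seed = config.seed

    filtered, report = run_qc(
        counts, min_cells_per_gene=config.min_cells_per_gene, mito_max=config.mito_max
    )
    norm = median_normalize(filtered)
    libsize = filtered.library_sizes()
    pcs = pca_libsize_regressed(
        norm, library_size=libsize, n_pcs=config.n_pcs_requested, seed=seed
    )
    var_mask = variable_genes(norm)

    imputed = impute(
        norm,
        library_size=libsize,
        k=min(config.impute_k, filtered.n_cells - 1),
        ka=config.impute_ka,
        t=config.impute_t,
        n_pcs=config.impute_n_pcs,
        seed=seed,
    )

    result = AnalysisResult(
        qc_report=report, filtered=filtered, variable_gene_mask=var_mask
    )

    if patient_ids is not None:
        patient_ids = pd.Series(list(patient_ids), index=counts.cell_ids)
        patient_ids = patient_ids.loc[filtered.cell_ids].to_numpy()

    if sigs is not None:
        scores = score_signature(imputed, sigs)
        assignment = fit_bgmm(
            scores, n_components=min(len(scores.columns), 4) if len(scores.columns) > 2 else 2,
            covariance="diagonal", seed=seed,
        )
        result.signature_scores = scores
        result.assignment = assignment
        if patient_ids is not None:
            result.fractions = bootstrap_fractions(
                assignment.labels,
                patient_ids,
                n_cells=config.bootstrap_n_cells,
                n_rounds=config.bootstrap_n_rounds,
                seed=seed,
            )
        # phenotypic volume per assigned class, on normalized UN-imputed
        # variably-expressed genes, controlled for group size
        expr = norm.values[:, var_mask]
        for cls in range(assignment.n_components):
            mask = assignment.labels == cls
            if mask.sum() < config.volume_n_cells:
                warnings.warn(
                    f"class {cls}: {mask.sum()} cells < {config.volume_n_cells}; "
                    "volume skipped"
                )
                continue
            result.volumes[cls] = volume_distribution(
                expr,
                cell_mask=mask,
                n_cells=config.volume_n_cells,
                n_repeats=config.volume_n_repeats,
                seed=seed + cls,
            )

    # diffusion geometry on PCs of the un-imputed normalized matrix
    n_pcs_graph = min(config.impute_n_pcs, pcs.scores.shape[1])
    dm = diffusion_map(
        pcs.scores[:, :n_pcs_graph],
        k=min(config.impute_k, filtered.n_cells - 1),
        ka=config.impute_ka,
        n_components=config.diffusion_components,
    )

    # archetypes on PCs of the imputed matrix
    pcs_imp = pca_libsize_regressed(
        imputed.values, library_size=libsize, n_pcs=config.n_pcs_requested, seed=seed
    )
    sel = select_n_pcs(pcs_imp.explained_variance_ratio, config.target_variance)
    X_arch = pcs_imp.scores[:, : max(sel.n_knee, 2)]
    chosen_K, ev_curve, models = select_n_archetypes(
        X_arch, archetype_k_grid, seed=seed
    )
    model = models[chosen_K]
    nbhd = archetype_neighborhoods(dm, model, X_arch)
    markers = archetype_markers(
        imputed,
        nbhd,
        gene_mask=var_mask,
        n_resamples=config.emd_n_resamples,
        seed=seed,
    )

    result.n_archetypes = chosen_K
    result.archetype_model = model
    result.neighborhoods = nbhd
    result.marker_table = markers
    return result
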