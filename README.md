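# umscape

Single-cell dissection of intra-tumor phenotypic heterogeneity, built for
droplet scRNA-seq of uveal melanoma but applicable to any tumor whose cells
lie on a continuum between transcriptional programs. Uveal melanoma is
clinically stratified into a low-risk (GEP1) and a high-risk (GEP2) class
from bulk expression of a 12-gene signature; a bulk label, however, only
reports the dominant subpopulation. `umscape` implements the per-cell
version of this analysis: every tumor cell gets a prognostic class, every
patient a class-fraction estimate with bootstrap confidence intervals, and
every tumor a scalar measure of how much transcriptional state space its
cells occupy — plus an unsupervised description of the extreme phenotypic
states bounding that space.

## What the package computes

**QC and normalization.** Ambient ("empty droplet") barcodes are removed at
the knee of the smoothed ECDF of log10 library size; apoptotic cells at
mitochondrial count fraction > 25%; low-complexity libraries by a robust
residual rule on genes-detected vs library size. Genes detected in < 10
cells, or with log10 total counts more than 5 SD below the second mode of a
two-Gaussian fit, are dropped. Counts are divided by per-cell totals and
rescaled by the median total; PCA (randomized SVD) is followed by OLS
regression of library size out of every component.

**Diffusion imputation.** A k-NN graph on the first 20 regressed PCs is
converted to affinities with an adaptive Gaussian kernel
`a(i,j) = exp(-d(i,j)^2 / sigma_i^2)` (`sigma_i` = distance to the ka-th
neighbor), symmetrized, and row-normalized into a Markov matrix `M`;
expression is denoised as `M^t X` with conservative defaults `t=3, k=27,
ka=12`.

**Per-cell prognostication.** Cells are scored by mean imputed expression
of each signature; a variational Bayesian Gaussian mixture over score space
(2 components, diagonal covariance for GEP1/GEP2; 4 components, spherical
or tied covariance for TCGA-like subtypes) assigns labels and posteriors.
Per-patient class fractions are estimated from 20 draws of 500 cells, with
percentile 95% CIs, to correct for unequal cell numbers.

**Phenotypic volume.** For a cell group, with `lambda_e` the eigenvalues of
the gene–gene covariance of the normalized *un-imputed* expression over
variably expressed genes,

    log(Volume) = sum_{lambda_e > 0} 0.5 * log10(lambda_e^2) / d,

the log pseudo-determinant normalized by the gene count `d`, computed over
100 subsamples of 150 cells so groups of different sizes are comparable.

**Diffusion geometry and archetypes.** Diffusion components `e_l` and
eigenvalues `lambda_l` of the Markov matrix define the multi-scale distance
`D(i,j)^2 = sum_l (lambda_l/(1-lambda_l))^2 (e_{l,i}-e_{l,j})^2` (a
single-diffusion-time mode `lambda_l^{2t}` is also provided). Principal
convex hull analysis (PCHA) factorizes the PC-space data as `X ~ X C S`
with column-stochastic `C` and `S`, placing K archetypes on the data's
convex hull; K is chosen at the knee of explained variance vs K. Each
archetype anchors a neighborhood of radius half the multi-scale distance to
its nearest fellow archetype, and marker genes are ranked by the mean earth
mover's distance between neighborhood and size-matched background
expression over 100 resamples.

A synthetic-atlas generator (`umscape.simulate`) plants all of this ground
truth — archetypal programs, class fractions, library sizes, ambient
barcodes, mitochondrial fractions — so every stage has a recovery test with
no downloads.

## Worked example

```python
import numpy as np
from umscape import *

# cohort with known prognostic fractions planted per patient
cm, truth = simulate_two_class(
    {"UM01": 0.25, "UM02": 0.85}, separation=3.0,
    params=TwoClassParams(n_cells_per_patient=1500, seed=0),
)
norm = median_normalize(cm)
imp = impute(norm, library_size=cm.library_sizes(), seed=0)
scores = score_signature(imp, two_class_signatures())
assign = fit_bgmm(scores, n_components=2, covariance="diagonal", seed=0)
est = bootstrap_fractions(assign.labels, truth.patient.to_numpy(),
                          n_cells=500, n_rounds=20, seed=0)
for p in ("UM01", "UM02"):
    m, (lo, hi) = est.mean(p, 1), est.ci(p, 1)
    print(f"{p}: GEP2 fraction {m:.3f} (95% CI {lo:.3f}-{hi:.3f})")

hi_grp = assign.labels == 1
vol_hi = volume_distribution(norm.values, cell_mask=hi_grp, n_cells=150, seed=0)
vol_lo = volume_distribution(norm.values, cell_mask=~hi_grp, n_cells=150, seed=0)
print(f"log phenotypic volume (median over 100 subsamples): "
      f"GEP1-like {np.median(vol_lo.volumes):.3f}, "
      f"GEP2-like {np.median(vol_hi.volumes):.3f}")
```

Output:

```
UM01: GEP2 fraction 0.235 (95% CI 0.221-0.263)
UM02: GEP2 fraction 0.868 (95% CI 0.842-0.888)
log phenotypic volume (median over 100 subsamples): GEP1-like 0.848, GEP2-like 0.845
```

The estimated GEP2 fractions bracket the planted 0.25 and 0.85; the two
classes here are equally dispersed by construction, so their phenotypic
volumes coincide — on real tumors this statistic is where prognostic groups
differ.

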