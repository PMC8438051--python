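# Methods

This note documents the models and numerical procedures implemented in
`umscape`, the defaults they ship with, and the reasoning behind design
choices where more than one defensible option existed.

## Quality control

**Cell selection (knee filter).** Viable cells are separated from ambient
barcodes on the empirical cumulative distribution of log10(total counts +
1), evaluated on a 100-point uniform grid and smoothed with a Gaussian
kernel of sigma = 2 grid steps. The smoothed ECDF's derivative is a density
estimate; its local maxima (relative prominence >= 5% of the tallest) are
the barcode populations. The cutoff is placed where the ECDF slope is
minimal between the ambient mode and the rightmost (cell) mode — the sign
change of the discrete second difference, i.e. the density valley. We
deliberately use the valley rather than the point of maximum positive
curvature: the curvature maximum sits on the lower shoulder of the
cell-library distribution and discards a substantial fraction of real
cells, whereas the valley separates the populations with near-zero loss on
planted mixtures. Two guards handle degenerate inputs: fewer than three
distinct totals, a unimodal density, or a valley shallower than half the
smaller mode's height all retain every barcode with a warning, because
there is no ambient population to remove.

**Low-complexity filter.** Genes detected scales with library size along a
power law, so we regress log(genes detected + 1) on log(total + 1) by OLS
and flag cells with residuals below -3 robust SDs (1.4826 x MAD). The
threshold is intentionally permissive (~0.1% false-flag rate on
homogeneous Poisson cells); the filter is recorded in the QC report and
can be disabled. Fewer than 10 cells skips the filter.

**Mitochondrial filter.** Cells with a mitochondrial count fraction
strictly above 0.25 are treated as apoptotic. The boundary is strict:
exactly 25% is retained. Mitochondrial genes are recognized by the "MT-"
symbol prefix (case-insensitive); if none are present the filter warns and
retains everything.

**Gene filters.** Genes detected in fewer than 10 cells are removed.
Additionally, a two-Gaussian model is fit by least squares to a 50-bin
histogram of per-gene log10 total counts (means initialized at the
25th/75th percentiles); genes below mu2 - 5*sd2 of the larger-mean
component are removed. If the fit fails or the distribution is degenerate,
only the detection rule applies. The same fitting routine drives
variable-gene selection on the distribution of per-gene SDs of normalized
expression, with threshold mu2 - 1.5*sd2; its fallback is the top SD
quartile. Note the thresholds are properties of the fitted second
component, so by construction they admit ~93% (1.5 SD) of that component,
not all of it.

## Normalization and PC space

Each cell is divided by its total molecule count and rescaled by the
median total of retained cells, so all rows sum to the median library
size; the operation is idempotent. PCA uses seeded randomized SVD (50
components requested by default); each score column is then replaced by
its OLS residual against (intercept, library size), removing the partial
correlation between components and cell size. Explained-variance ratios
are recorded before regression. The number of PCs to use downstream is
reported two ways: the knee of the cumulative explained-variance curve
(max perpendicular distance to the chord, with the origin — zero PCs, zero
variance — prepended so a dominant first component registers at n = 1) and
the smallest n reaching a target fraction (default 90%). Uniform spectra
have no knee and fall back to the target rule.

## Diffusion imputation

The cell graph lives on the first 20 regressed PCs. For cell i with scale
sigma_i = distance to its ka-th nearest neighbor, affinity(i,j) =
exp(-d(i,j)^2 / sigma_i^2) over the k-NN edge set (k = 27, ka = 12 by
default), zero diagonal, symmetrized as (A + A^T)/2, then row-normalized
into a Markov matrix M. Imputed expression is M^t X with t = 3, computed
as t sparse multiplications — M^t is never formed. Duplicate points give
sigma = 0 and are assigned the smallest positive neighbor distance with a
warning; an isolated cell (zero affinity row) is an error naming the
barcode. Because M is row-stochastic, imputation is a convex combination:
constant genes are preserved exactly and no value leaves the input
column's range. The percentile-rescaling step some imputation variants
append is omitted. The same ka = 12 serves both the imputation and the
visualization/diffusion-map kernels; both knobs are exposed.

## Graph clustering and annotation

Communities are found on the k-NN graph re-weighted by Jaccard overlap of
neighbor sets, using seeded Leiden modularity maximization (the optimizer
is a pluggable contract: anything deterministic under a seed that
maximizes modularity). Graph connectivity is checked and warned about.
The neighborhood size k is selected by clustering over a k grid, computing
the pairwise ARI matrix, and taking the smallest k whose median ARI
against all larger k exceeds 0.75 — the scan matrix is returned so the
aggregation rule can be audited; if no k qualifies the largest is used
with a warning. Cluster annotation correlates centered cluster medians of
imputed expression with a centered bulk reference (genes x cell types)
over shared genes, using Pearson r with the exact t-transform p-value
(n-2 df); only |r| > 0.2 with p < 0.01 is displayed.

## Prognostic classification

Signature scores are unweighted means of imputed expression over each
signature's genes present in the matrix (absent genes dropped with a
warning; zero overlap is an error). The classifier is a variational
Bayesian Gaussian mixture with a fixed component count,
Dirichlet-distribution weight prior of 1/n_components, k-means
initialization under a fixed seed, and covariance diagonal (2-class),
spherical (4-class) or tied (4-class, for sparser validation cohorts).
Scores enter the fit unstandardized; a standardize option exists but is
off by default since the score columns share units. Components carry no
intrinsic identity, so after fitting they are relabeled by ascending mean
along the class-defining axis (by default the last score column, i.e. the
aggressive-signature axis): label K-1 is always the class highest on that
axis. Identical scores for all cells are rejected as unclassifiable.

Per-patient class fractions are means over 20 rounds of 500 sampled cells
with percentile (2.5/97.5, interpolated) CIs. Draws are without
replacement when a patient has >= 500 cells and with replacement otherwise
so the draw size — and hence the sampling variance being equalized across
patients — stays fixed; each such patient is logged.

## Phenotypic volume

For a cells x genes matrix of normalized, un-imputed expression restricted
to variably expressed genes, the statistic is sum over retained
eigenvalues of 0.5*log10(lambda^2), divided by the total gene count d.
Eigenvalues come from the singular values of the centered matrix (lambda =
s^2/(n-1), the unbiased covariance estimator) — the d x d covariance is
never materialized. "Nonzero" means lambda > max(lambda) * 1e-10; the
count of retained eigenvalues is reported so rank deficiency (n < d, rank
<= n-1) is visible. Normalization is by d, not by the retained rank; with
150-cell subsamples and thousands of genes the two differ materially and
the gene count is the stated convention. Imputation is never applied here
because diffusion smoothing rewrites the gene-gene covariance this
statistic measures. Group comparisons use 100 subsamples of 150 cells
drawn without replacement (groups smaller than the subsample are an error
— the fixed size is the cell-number control); subsample indices are sorted
so the single-possible-subset case is bitwise reproducible.

## Diffusion maps and multi-scale distance

The diffusion map eigendecomposes the same adaptive-kernel Markov matrix,
built on PCs of the *un-imputed* normalized matrix. Numerically we work on
the symmetric conjugate D^{-1/2} A D^{-1/2} (guaranteed real spectrum,
stable Lanczos), convert eigenvectors v back to right eigenvectors
D^{-1/2} v of M, and normalize each to unit length. A disconnected graph
would yield multiple unit eigenvalues and is an error listing component
sizes. The trivial lambda = 1 component is dropped; the embedding
dimension is the largest eigen gap among the leading eigenvalues (capped,
default cap 10), or a fixed L (the pipeline default is 5).

Distances weight component differences by lambda/(1-lambda) — the closed
form of the geometric series of single-time weights lambda^t over all t —
which avoids committing to a diffusion time and is robust to density
differences. The printed single-time form D^2 = sum_l lambda_l^{2t}
(e_{l,i}-e_{l,j})^2 is available as `mode="single-t"`. Both are Euclidean
metrics in a rescaled embedding, so symmetry and the triangle inequality
hold by construction (and are tested exhaustively on a small fixture).

## Archetypal analysis

PCHA minimizes ||X - XCS||_F^2 over C >= 0 (n x K, columns summing to 1
within a delta relaxation, default delta = 0) and S >= 0 (K x n, columns
summing to 1), so archetypes Z = X^T C lie in the data's convex hull and
each cell is a convex mixture of archetypes. The solver alternates
projected-gradient steps: each raw gradient is first projected onto the
tangent space of the column simplex (subtracting the weight-weighted
column mean), then stepped, clipped at zero, and renormalized; per-factor
step sizes grow 1.2x on success and halve on failure, and a step is only
accepted if the objective decreases — the SSE history is therefore
monotone non-increasing by construction, which is also the convergence
certificate (relative change < 1e-8, max 400 iterations; non-convergence
returns the best iterate with a flag). C is seeded by FurthestSum (greedy
maximum-sum-of-distances over data points, first point re-picked) and S by
hard assignment to the nearest initial archetype. Explained variance is
1 - SSE/||X - mean||^2.

The archetype number is scanned over an ascending K grid with warm starts:
the K-model starts from the (K-1)-model plus the worst-reconstructed data
point as a new archetype, which makes the explained-variance curve
monotone non-decreasing by construction. The selected K is the knee of
log(1 - EV) versus K (the shared max-distance-to-chord utility applied to
log residual variance). On the raw EV curve the early steep gains dominate
the chord geometry and the knee lands one short of the true archetype
count on planted simplices; residual variance on the log scale isolates
the saturation point. PC selection keeps the raw cumulative curve, where
the closed-form behavior is correct.

**Neighborhoods.** Each archetype is anchored at its Euclidean-nearest
cell in PC space (two archetypes sharing an anchor is an error); its
radius is half the multi-scale distance to the nearest other anchor, so
neighborhoods are disjoint by construction and span comparable manifold
ranges; members are cells within the radius, and separately every cell is
assigned to its multi-scale-nearest anchor.

**Markers.** Per archetype and gene, the score is the earth mover's
distance between neighborhood expression (imputed, variably expressed
genes) and an equal-sized background drawn from non-members, averaged over
100 background draws. Since the two samples always have equal size, the
1-D Wasserstein-1 distance reduces to the mean absolute difference of
order statistics, which we compute vectorized across genes; the
general-purpose `emd_score` uses the standard CDF-based routine. A
neighborhood larger than its complement draws background with replacement
(warned). Scores are reported as means, not p-values.

## Synthetic data

The generator produces what the pipeline assumes and nothing more: tumor
cells whose expression rates are Dirichlet-weighted convex combinations of
K archetypal programs; a minority non-tumor population with its own marker
block; lognormal library sizes (default median 2000, log-SD 0.35,
matching a typical droplet experiment); Poisson counts, with optional
negative-binomial overdispersion via a Gamma-Poisson mixture; a
mitochondrial gene block receiving a Beta-distributed fraction of each
cell's rate mass (mean 5%, with a designated 2% apoptotic subpopulation at
mean 40%, well past the 25% rule); and ambient barcodes drawn from the
mean cell profile at 2.5% of a typical library (~50 counts). The
two-class generator plants per-patient GEP2-like fractions; "separation"
is the per-gene effect size in units of the per-gene lognormal noise SD
(0.5), applied to each class's own 12-gene block, so separation 0 is
exactly the null. The simplex generator draws Dirichlet combinations of
random vertices plus isotropic noise for archetype-recovery tests.

What the generator does *not* emulate: doublets, batch effects,
ambient-RNA contamination of real cells, gene-gene correlation beyond the
program structure, or realistic gene-count scales (hundreds of genes, not
~15k). Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated statistical assumptions, not robustness to
every artifact of real droplet data.

## Problem sizes and determinism

The test suite and the acceptance script run desk-scale versions of each
analysis: 11,000-barcode QC mixtures, 12,000-cell two-class cohorts,
2000-point simplices over five seeds, and a 3000-cell end-to-end atlas —
sizes chosen so the full suite completes in about half a minute while
keeping every estimate's sampling error well inside its test tolerance.
Every stochastic stage takes an explicit seed, and a serialized RunConfig
fully determines a run; the end-to-end pipeline is bitwise reproducible
under a fixed config.

## Known limitations

- The complexity filter and the knee discretization are stand-ins for
  intent-level descriptions; both are recorded in the QC report so they
  can be audited or disabled.
- The 5-SD gene rule operates on the per-gene log10 total distribution; a
  rank-plot (log-log axes) reading of the same rule is possible and would
  shift the fitted modes.
- Modularity-based community detection over-partitions when the
  neighborhood size is small relative to true cluster sizes; the ARI
  stability scan is the guard, not a guarantee.
- PCHA solves a non-convex problem; warm-started scans make the EV curve
  monotone, but individual fits can converge to local optima for poorly
  separated archetypes.
- Survival analysis on the resulting strata, copy-number inference, and
  2-D layout computation are out of scope.
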