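# Methods

This note documents the models, defaults and design decisions behind
`blineage`, and what the synthetic benchmarks do and do not demonstrate.

## Developmental classifier (CyTOF arm)

**Model.** Healthy bone marrow is partitioned into 15 developmental
populations (pre-pro-B through pro-B/pre-B/immature/mature stages, plus
early-non-B and non-B fractions). Each population contributes a mean
vector and covariance matrix over the ten gating proteins (CD19, CD20,
CD24, CD34, CD38, CD45, CD127, CD179b, IgMi, TdT) in arcsinh space
(cofactor 5). A query cell is assigned to the population with the
smallest Mahalanobis distance, or "unclassified" when every distance is
at least the threshold (default 10, matched to the ten dimensions and
applied to the distance, not its square).

**Regularization.** Gated populations can be small relative to ten
dimensions, so the sample covariance S (ddof = 1) is shrunk as
`(1 − λ)·S + λ·diag(S) + ε·I` with λ = 0.1 and ε = 1e-6·mean(diag S).
This keeps every Σ_k positive definite (a 5-cell population in 10
dimensions still factorizes) while perturbing well-estimated covariances
negligibly. λ = 0 recovers the textbook estimator exactly up to the ε
ridge. Covariances are population-specific rather than pooled: distances
are meant to respect each population's own geometry. Both λ and the
choice of per-population covariance are configurable.

**Numerics.** Distances go through a cached Cholesky factor
(`solve_triangular`), never an explicit inverse; tests verify agreement
with a dense-inverse oracle to 1e-8 relative. Ties in the argmin go to
the earlier population in the model's declared order — a measure-zero
event that the tests nevertheless construct. Assignments are invariant
under a joint invertible linear map of reference and query when λ = 0.

## Preprocessing

Raw ion counts are arcsinh-transformed (`asinh(x/5)`); the transform
state is recorded on the matrix and double application is an error. Per-
population summaries are medians (even-count convention: mean of the two
middle values). Subsampling (default 1000 cells) is uniform without
replacement, stratified per population or per sample at the caller's
choice — the convention differs between use cases, so both are exposed.

## Healthy-reference projection (CITE-seq arm)

PCA is fitted on healthy cells only, over the 3000 most-variable genes
(ranked by plain variance of the normalized expression; a fitted
mean–variance trend would also be defensible, but the simple statistic
is transparent and is the documented, swappable default) concatenated
with CLR-transformed antibody tags, unweighted. Features are centered
with healthy means (optionally standardized; default center-only) and
the top 30 components retained, with a sign convention (largest-
magnitude loading positive) so refits are bit-identical. Query cells are
*predicted* into this space: `(query − healthy_center) · loadings`.
Model features missing from a query are imputed as the healthy feature
mean (zero after centering) with a warning; more than 50% missing is an
error. Any nonlinear embedding is display-only — every assignment
happens in the 30-PC coordinates.

Assignment is an exact (brute-force) Euclidean 10-nearest-neighbor
majority vote over healthy cells. Vote ties are broken by the smaller
mean distance to the tied label's voting neighbors, then by label order.
A stratified 10-fold CV accuracy over the healthy labels is computed as
a diagnostic (folds are seeded and reduced with a warning when a
population has fewer cells than folds); the final index uses all cells.

## Expression stage

**QC.** A cell is removed when it has fewer than 500 expressed genes OR
fewer than 200 total molecules OR a mitochondrial count fraction above
50%. The OR-combination is the standard QC semantics; the alternative
reading ((genes OR counts) AND mito) is available behind
`rule="genes_or_counts_and_mito"`. The report enumerates removals per
criterion.

**Normalization.** Counts are scaled per cell to 10,000 and
log1p-transformed, then each gene is regressed on the per-cell
mitochondrial fraction and the covariate contribution
`b·(mito − mean)` subtracted, preserving gene means while removing the
confounding trend. This is a deliberately simple, fully documented
normalization in the spirit of regularized-NB variance stabilization; it
is *not* a reimplementation of such a transform, and the recipe string is
stamped into the output's metadata. Antibody tags use the centered
log-ratio: `ln(x+1) − mean_tags ln(x+1)` per cell.

**Differential expression.** Two-sided Wilcoxon rank-sum with normal
approximation, tie and continuity correction (scipy); a gene is tested
only if expressed in ≥ 10% of cells of at least one group; significance
additionally requires |log2 FC| ≥ log2(1.25) and Bonferroni-adjusted
p < 0.05 with m = number of tested genes. Fold change is the ratio of
expm1-scale group means with pseudocount 1e-9 (negative post-regression
residual means are clipped at zero first). Every non-significant gene
carries a reason code (`frac`, `fc`, `alpha`). A cross-check test
verifies the p-values against an independent single-cell framework's
Wilcoxon implementation (within the ~1% continuity-correction
difference) and against an exact permutation oracle at small n.

**Module score.** Genes are binned by average expression into 24
rank-based equal-count bins; each signature gene draws 100 control genes
from its bin (excluding signature genes; with replacement only when the
bin is too small), and the score is mean(signature) − mean(controls) per
cell. The draw is seeded and the chosen controls are exposed in the
result's attrs. The expectation for a random gene set is zero.

## Intron retention (splicing arm)

All intervals are 0-based half-open; GTF is converted on I/O and strand
is ignored (retention counting is strand-symmetric given a gene model).
For a target intron with flanking exons:

- **inclusion-supporting (I)** — reads with ≥ 1 aligned base inside the
  intron; contiguous reads crossing an exon–intron boundary necessarily
  align into the intron, so they are included by construction;
- **skipping (S)** — reads with a junction gap exactly matching the
  intron (a read whose gap merely *covers* the intron without matching
  its boundaries counts in neither class);
- **flanking-exon (E)** — reads whose blocks lie entirely within the two
  flanking exons with no gap covering the intron.

No read can be both I and S. Two summaries are emitted: the bounded
retention ratio I/(I+E) (with the raw I/E quotient alongside, since the
denominator convention of a ratio of this kind is ambiguous), and the
length-normalized inclusion level ψ = (I/l_I)/(I/l_I + S/l_S) with
effective lengths l_I = intron_length + L − 1 and l_S = L − 1 for read
length L — the start-position counts of a uniquely placed single-end
read. Group comparison pools length-normalized counts per event and uses
a two-proportion z-test with Benjamini–Hochberg correction across
events; this is an explicit screening stand-in, not a splicing
likelihood model. Degenerate events (zero counts) are NA and excluded
from the corrected family.

## Synthetic data: what it emulates, and what it does not

The generators define the conditions under which the pipeline is
validated:

- **Healthy reference.** 15 populations with hand-crafted 10-marker
  arcsinh profiles sketching normal B lymphopoiesis (CD34/TdT early,
  CD179b in pro/pre stages, surface IgM from the immature stages,
  CD20/CD45 rising toward maturity), with IKAROS/CD22/PAX5 riding along
  for shift experiments. Marker noise is multivariate normal
  (default isotropic, σ = 0.35) — chosen because the classifier consumes
  arcsinh-space Gaussian geometry, not because CyTOF noise is Gaussian.
  Every pair of populations differs by ≥ 2 arcsinh units on ≥ 2 markers,
  which makes classification well-posed at the default noise; harder
  geometries are a config away.
- **Cohorts.** Samples are multinomial population mixtures; a planted
  shift adds a constant to one marker in one population of one group
  (default: −1.0 arcsinh IKAROS in relapse pro-BII), mirroring the
  contrast between complete-remission and antigen-negative-relapse
  groups.
- **Counts.** Negative binomial (gamma–Poisson) with gene-level
  dispersion 0.1 and log-normal library sizes (σ = 0.3) — the minimal
  standard scRNA count model. Planted DE genes and signatures multiply
  baseline means in one condition; mitochondrial content is steered to
  per-cell target fractions. Eight antibody tags are generated alongside.
- **Reads.** Uniquely placed single-end reads, no sequence content or
  errors (the splicing stage consumes intervals). Each read is
  retention-supporting with probability ψ·l_I/(ψ·l_I + (1−ψ)·l_S) — a
  uniform draw from a transcript pool containing a ψ fraction of
  intron-retaining molecules — so the length-normalized estimator is
  consistent by construction.

None of this models doublets, batch effects, ambient RNA, zero-inflation
beyond NB, marker correlation structure, or mappability: passing the
benchmarks shows the *procedures* are implemented correctly and recover
planted truth under clean conditions, not that they are robust to every
artifact of real cytometry or sequencing data.

## Benchmark problem sizes

The evaluation pipelines (`blineage.pipelines`, driven by
`scripts/acceptance.py` and the recovery test suite) use: 500 query
cells for the classifier-oracle check; 100 cohorts of 6 CR vs 11 relapse
samples × 2,000 cells for the IKAROS-shift contrast; 2,000 healthy cells
for projection exactness; 100 CITE-seq replicates of 300 + 300 tumor
cells against a 750-cell, 400-gene healthy reference for the
IKZF1/signature contrast; 200 null and 100 power replicates of 2,000
genes × 400 cells for DE error control; and depth 10,000 per intron for
estimator accuracy. These sizes give the recovery rates comfortable
binomial margins while keeping a full run to a few minutes.

## Known limitations

- The mitochondrial-fraction regression is linear and per-gene; strongly
  nonlinear confounding would leave residual structure.
- The two-proportion splicing comparison ignores within-group
  overdispersion across samples; with many samples per group a
  replicate-aware model would be preferable.
- The module score matches controls on mean expression only, not on
  variance or dropout rate.
- The classifier threshold (10) is a convention tied to the 10-marker
  panel; other panels need their own threshold.
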