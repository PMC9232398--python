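# Methods

This note documents the statistical models implemented in `diffomics`, the
defaults and numerical choices, what the synthetic cohort generator does and
does not emulate, and the known limitations.

## Survival dichotomization

At a horizon *t* (years), a sample is labeled 1 (short survival) if its
event occurred at or before *t*, and 0 (long survival) if its observed time
exceeds *t*, regardless of event status. A sample censored at or before *t*
has an unknown *t*-year status; it is excluded from classification and
listed in `LabeledDataset.excluded_samples`. Including such samples under
either label would inject label noise; exclusion is the package's documented
choice. Time units are converted to years on ingestion (`time_divisor` = 1
for years, 12 for month fields, 365.25 for day fields).

## Preprocessing

Expression tables are read genes-in-rows, oriented samples × genes in
memory. Genes with ≥ 5% missing values are removed; remaining missing cells
are filled with the gene's median over observed samples. Repeated sample ids
are averaged. FPKM is converted to TPM by per-sample normalization to 10⁶
(exact column-sum contract, idempotent up to scale). CNV calls are binarized
as `value != 0` (copy number out of the normal range); a MAF-like mutation
table maps to a 0/1 matrix with entry 1 iff at least one record exists for
the (sample, gene) pair. Missing-value tokens accepted: `NA`, `NaN`, `nan`,
empty cell.

## DC-SIS screening

Genes are ranked per omics layer by empirical distance correlation with the
observed survival time of all samples. The V-statistic form is used:
`dcov²(u, v) = mean(A ∘ B)` with A, B the double-centered |uᵢ − uⱼ| distance
matrices; `dcor = dcov(u,v)/√(dcov(u,u)·dcov(v,v))`, defined as 0 when a
marginal distance variance vanishes. Distances are Euclidean on scalars; the
response is used untransformed in years. Screening ignores censoring status
— a deliberate simplification (the marginal utility ranking, not a hazard
model), noted as a limitation below. The screening size *d* defaults to
⌊n / log n⌋; ties in dcor break by gene-id lexicographic order so rankings
are deterministic. Binary layers are screened on their 0/1 values directly.
The per-layer selections are intersected to give the common gene set used
by both differential-network models.

## JDINAC

For each screened gene pair, class-conditional bivariate densities are
fitted with a Gaussian product kernel; per-axis bandwidth follows the normal
reference rule h = σ̂ · n^(−1/6), floored at 1e-6·(range + 1) for degenerate
axes. Density evaluations are floored at ε = 1e-10 so log-ratios stay
finite. For strictly positive matrices (TPM-like expression) the densities
are fitted on log-transformed values: the population log density ratio is
invariant under a common monotone transform (the Jacobians of f and g
cancel), while the finite-sample KDE is far better behaved on the
symmetrized scale than on skewed positive data. This transform is automatic
and can be overridden (`log_scale=`).

Each of `n_splits` (default 100) stratified half/half splits fits densities
on one half and the penalized logistic regression on the other. Features are
standardized before the L1 fit (as lasso-logistic practice dictates); the
penalty is chosen per split by internal 5-fold cross-validated deviance with
the one-standard-error rule over an 7-point grid C ∈ logspace(−2, 1). Both
the half/half partition and the inner folds are built by per-class walks of
a single seeded permutation, which makes them invariant under relabeling the
classes; combined with the sign symmetry of the L1 objective this gives the
exact label-swap property (swapping classes flips every predicted
probability to 1 − p). Final predictions are the mean over split models;
`edge_counts` tallies the splits in which a pair's coefficient is nonzero,
and the default edge threshold is 10% of the splits (the full ranking is
always emitted). No clinical covariates enter the logit.

## LGCDG

Binary data are modelled per class as D_j = I(X_j > C_j) with X a latent
non-paranormal vector, Λ_j = f_j(C_j) the threshold on the Gaussian scale.
Estimation proceeds in three steps:

1. **Thresholds.** Λ̂_j = Φ⁻¹(1 − p̂_j) with p̂_j the column one-rate,
   Winsorized to [1/(2n), 1 − 1/(2n)].
2. **Latent correlations.** Pairwise Kendall's tau-a (ties contribute 0;
   closed form 2(n₁₁n₀₀ − n₁₀n₀₁)/(n(n−1)) for binary columns; diagonal set
   to 1 by convention) is inverted through the bridge
   τ = 2(Φ₂(Λ_j, Λ_k; σ) − Φ(Λ_j)Φ(Λ_k)), which is strictly increasing in
   σ, by monotone bisection to 1e-10. Φ₂ is evaluated with the
   single-integral identity under the t = sin θ substitution and 64-point
   Gauss-Legendre quadrature (absolute error well below 1e-12). A tau
   outside the attainable range is clamped to a latent correlation of
   ±(1 − 1e-6) with a warning. The matrix is then projected to the nearest
   positive-definite correlation matrix by eigenvalue clipping at δ = 1e-3
   with diagonal renormalization (iterated to convergence).
3. **Precision difference.** Δ̂ solves min Σ|Δ_jk| subject to
   |(b̂¹ ⊗ b̂⁰) vec(Δ) − vec(b̂¹ − b̂⁰)|_∞ ≤ λ_n, as an exact linear
   program (HiGHS). Post-screening dimensions are tens of genes, so the LP
   is exact and fast; dimensions above 50 are rejected rather than solved
   approximately. The solution is symmetrized by keeping, per pair, the
   entry of smaller magnitude (conservative for support), and entries below
   1e-11 are set to exactly 0. λ_n defaults to 2·√(log p / min(n₁, n₀)); a
   grid scan is available that picks the sparsest fit whose reconstruction
   residual stays within 10% of the tightest fit.

**Sign convention.** The constraint above algebraically identifies
Δ = (Σ⁰)⁻¹ − (Σ¹)⁻¹. Edge support and magnitudes — everything the pipeline
uses — are unaffected by the overall sign; reported signs follow the
constraint as written.

Binary columns with fewer than 2 ones or 2 zeros in a class give degenerate
tau estimates and are dropped from Δ estimation (logged).

## Network assembly and hubs

Edges are identified by gene-symbol pair only; per-layer weights (edge
counts for expression, |Δ| for binary layers) are retained as attributes.
The combined differential network keeps pairs supported by ≥ 2 omics layers
(with exactly two layers this is an AND rule). Hub genes have degree ≥ 3 in
the combined network; the consensus reports hubs appearing in ≥ 2 horizon
networks. Exports: GraphML and SIF (Cytoscape-ingestible), with round-trip
readers.

## Evaluation

Stratified k-fold (default 5) cross-validation, deterministic given the
seed; the full JDINAC split protocol runs inside each training fold. AUC is
the rank (Mann-Whitney) estimator with ties counted ½, identical to
trapezoidal integration of the empirical ROC. The risk cutoff maximizes
Youden's J = tpr − fpr, ties resolved toward the smaller (more sensitive)
threshold; probability ≥ cutoff ⇒ high-risk. Kaplan-Meier curves and the
unweighted two-sample log-rank test (via lifelines) compare the risk
groups on the full right-censored follow-up. Cross-validated probabilities
are used for the KM split by default (honest evaluation); resubstitution
probabilities are available by evaluating `JdinacModel.mean_probability`.

## Synthetic cohorts

The generator emulates the structure the models assume, with defaults chosen
to resemble a desk-scale tumor cohort:

- **Expression:** per class, a multivariate Gaussian with unit variances and
  configured pairwise correlations, exponentiated (log-normal marginals,
  TPM-like positive scale). Marginals are identical across classes, so only
  pairwise dependence carries class signal.
- **Binary layers:** per class, a latent Gaussian with covariance equal to
  the inverse of a configured precision matrix (identity plus off-diagonal
  entries), thresholded at the per-gene marginal quantile (default 0.7 for
  CNV ≈ 30% alteration rate, 0.9 for mutation ≈ 10%). Because diagonal
  rescaling preserves zero patterns, the true differential-precision support
  equals the set of pairs whose configured entries differ whenever
  non-differential pairs are zero in both classes (the case in all shipped
  configurations).
- **Survival:** exponential event times with per-class hazard (defaults
  0.7/yr for class 1, 0.1/yr for class 0) under independent exponential
  censoring (default 0.05/yr).

Not emulated: realistic allele frequencies, expression mean shifts between
classes, tumor subtype structure, batch effects, or dependence between
layers beyond the shared class label. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not robustness to
real-data violations of those assumptions.

## Study problem sizes

The test suite and `scripts/acceptance.py` use fixed study sizes chosen as
the smallest designs at which each property is comfortably identifiable:

- screening-oracle agreement: 50 random instances, n ≤ 30;
- sure screening: 5 active genes of 200 (each sharing √0.3 correlation with
  the response), n = 200, 100 seeded runs, top-20 retention;
- bridge recovery: ρ ∈ {0, 0.5, 0.9} closed-form inversion; rank-based
  recovery of σ = 0.5 at n = 2000, 20 seeds;
- differential-precision recovery: p = 10, n = 500 per class, two planted
  pairs with precision entries ±0.6, 20 replicates;
- classifier calibration and power: 6-gene panels (the post-screening scale
  at which pair densities are well estimated), n = 200 exchangeable null and
  n = 400 planted-pair cohorts, 25 data splits, 20 replicates each;
- end-to-end pipeline: n = 240, 8 genes, one pair planted in all three
  layers, hazards 2.0 vs 0.02 /yr, 5-year horizon.

## Limitations

- Screening ranks genes against observed time ignoring censoring; heavily
  censored cohorts bias the ranking toward censoring-time correlates.
- The latent-correlation clamp at ±(1 − 1e-6) can produce near-singular
  inputs to the Δ program on very sparse binary layers; the low-prevalence
  filter mitigates but does not eliminate this.
- The LP solver is exact but dense; it is restricted to the post-screening
  regime (p ≤ 50).
- Horizon networks are estimated independently; no information is shared
  across horizons beyond the hub consensus.
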