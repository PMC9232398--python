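# diffomics

Differential-network analysis of survival-dichotomized multi-omics cohorts.

Cancer cohorts such as TCGA-BRCA or METABRIC provide, for the same patients,
continuous gene expression (FPKM/TPM), copy-number variation calls, somatic
mutations, and overall-survival follow-up. `diffomics` asks which *gene-gene
interactions* — not which individual genes — differ between patients with
short and long survival, integrates the answer across omics layers, and
evaluates how well the interaction signal predicts the dichotomized outcome.
It is a library first (importable API plus the short scripts in
`examples/`), with a thin `diffomics` command for running the pipeline from
a shell.

## What it computes

Patients are labeled at a horizon *t* ∈ {1, 3, 5, 10} years: label 1 if the
event occurred at or before *t*, label 0 if survival exceeds *t* (patients
censored before *t* are excluded). Then, per horizon:

1. **DC-SIS screening.** Each gene in each omics layer is ranked by its
   empirical distance correlation with survival time,
   dcor(u, v) = dcov(u, v) / √(dcov(u, u) · dcov(v, v)),
   computed with the double-centered pairwise-distance V-statistic. The
   top-*d* genes per layer are intersected across layers.
2. **JDINAC** (continuous expression). For each screened gene pair (i, j),
   class-conditional bivariate kernel densities f_ij (short survival) and
   g_ij (long survival) are fitted; the features ln f_ij(x_i, x_j)/g_ij(x_i, x_j)
   enter an L1-penalized logistic regression
   logit(P) = β₀ + Σ_{i<j} β_ij ln f_ij/g_ij,  Σ|β_ij| < c,
   over 100 stratified half/half data splits (densities on one half,
   regression on the other). Predictions are averaged over splits; the
   number of splits with β_ij ≠ 0 is the pair's edge count.
3. **LGCDG** (binary CNV/mutation). Binary calls are modelled as latent
   Gaussian copula variables D_j = I(X_j > C_j). Kendall's tau is inverted
   through the bridge function τ = 2(Φ₂(Λ_j, Λ_k; σ) − Φ(Λ_j)Φ(Λ_k)) to
   estimate per-class latent correlation matrices b̂¹, b̂⁰, and the
   precision-matrix difference Δ is estimated by
   argmin |Δ|₁ subject to |(b̂¹ ⊗ b̂⁰) vec(Δ) − vec(b̂¹ − b̂⁰)|_∞ ≤ λ_n,
   solved exactly as a linear program.
4. **Network assembly.** Per-layer differential edges are combined; an edge
   is kept if supported by ≥ 2 omics layers, genes with degree ≥ 3 are hub
   genes, and hubs recurring in ≥ 2 horizon networks form the consensus.
5. **Evaluation.** Stratified 5-fold cross-validation, ROC/AUC (rank
   estimator), Youden-index cutoff, confusion metrics, and Kaplan-Meier +
   log-rank comparison of the cutoff-defined risk groups.

A synthetic cohort generator (`diffomics.simulate`) produces cohorts with
exactly the generative structure these models assume — class-dependent
pairwise expression correlation, thresholded latent-Gaussian binary layers
with configurable precision differences, and per-class exponential survival
— so the entire pipeline is testable without downloading any cohort.

## Worked example

`examples/03_jdinac.py` plants a single differential pair (correlation +0.8
in the short-survival class, −0.8 in the long-survival class; all marginal
distributions identical) among 6 genes, n = 400:

```
edge counts over 25 data splits (top 3 of 15 pairs):
gene_i gene_j  edge_count  mean_abs_coef
    G0     G1          25       3.886401
    G2     G3          17       0.189287
    G0     G5          14       0.109179

5-fold CV AUC: 0.895  (Youden cutoff 0.484)
accuracy 0.820, sensitivity 0.810, specificity 0.830
```

The planted pair G0–G1 is selected in every split with a dominant
coefficient, and the cross-validated AUC approaches the Bayes limit (~0.90)
for this configuration. `examples/05_full_pipeline.py` runs the whole
pipeline on a cohort with the same pair planted in all three layers:

```
     auc  accuracy  sensitivity  specificity   cutoff    logrank_p
0.824261  0.759804     0.728972     0.793814 0.512572 7.486796e-13

combined differential network: 6 edges
planted pair present: True (layers: ['cnv', 'mrna', 'mutation'])
hub genes (degree >= 3): ['G0']
```

The pair survives the ≥ 2-omics rule, and the risk groups split by the
ROC-derived cutoff separate sharply on the Kaplan-Meier curves.

## Command line

```sh
diffomics simulate --seed 1 --outdir cohort/          # write a synthetic cohort
diffomics run-all --config config.yaml                # full pipeline
diffomics screen --matrix expr.tsv --clinical clin.tsv --out screening.tsv
```

Subcommands `preprocess`, `jdinac`, `lgcdg`, `network`, and `evaluate` run
individual stages; every flag mirrors a key of the YAML config file.

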