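# cncl

Breast-cancer cells fall into two transcriptional states with very different
drug sensitivities: a cancer-stem-cell-like, mesenchymal state (**CS/M**) and
a non-stem, epithelial state (**NS/E**). Tumors move between the two
(epithelial–mesenchymal transition and its reverse), often in response to
therapy, which makes the state — and its plasticity — worth measuring.
`cncl` is a pipeline for doing that from bulk or single-cell expression data
with a small directional gene signature:

- **Signature derivation** from two independently labeled cohorts: per-gene
  Welch t-tests (top 200 at p < 0.05 per dataset), direction-concordant
  intersection, hard filters (fold change ≥ 3, p < 2×10⁻⁴ in both datasets),
  and a within-arm inter-gene correlation filter. On the planted synthetic
  benchmark this yields the canonical 15-gene list (8 up, 7 down in CS/M).
- **Categorical classification** by complete-linkage Euclidean hierarchical
  clustering on the standardized signature submatrix, with a cluster-polarity
  rule naming the CS/M and NS/E clusters (and an intermediary cluster at
  k = 3), plus a cross-platform consistency audit.
- **A continuous stemness score.** Per-gene medians of z-scored expression in
  each reference group give two centroids; each sample's standardized
  signature vector is Pearson-correlated with both, and

  SS = Δr = r(sample, CS/M centroid) − r(sample, NS/E centroid) ∈ [−2, 2],

  negative meaning more epithelial. Paired pre/post designs are traced for
  phenotype switching.
- **Drug-response fitting**: a six-model logistic ensemble
  ({hill free, hill = 1} × {unconstrained, top = 100, bottom = 0}) fit by
  nonlinear least squares on log dose; the model with the lowest residual
  standard error supplies the IC50 (relative, midpoint convention, with a
  "> max dose" sentinel) and the activity area (mean inhibition over tested
  doses). A Welch-t screen finds phenotype-differential drugs.
- **Survival analysis**: two-group log-rank, a multiple-cutoff log-rank scan
  (LRMC) that dichotomizes Δr at a percentile grid with a group-size guard
  and an optional permutation-adjusted minimum p, and multivariate Cox
  regression with clinical covariates.
- **Synthetic data** for every stage with planted ground truth (differential
  expression with correlated signature arms, paired phenotype switching,
  4-parameter-logistic viability, two-group exponential survival).

## Worked example

```python
from cncl import *

# two labeled cohorts with a planted 8-up/7-down signature
a_mat, a_lab, truth = generate_expression(ExpressionSimConfig(n_genes=300, noise_sd=0.25, seed=11))
b_mat, b_lab, _     = generate_expression(ExpressionSimConfig(n_genes=300, noise_sd=0.25, seed=22))
sig = derive_signature(a_mat, a_lab, b_mat, b_lab)
print(f"signature: {len(sig)} genes ({len(sig.up_genes)} up, {len(sig.down_genes)} down in CS/M)")

# score a paired pre/post-treatment cohort (14 NS/E + 4 CS/M tumors) and
# trace therapy-induced phenotype switching
cent = build_centroids(a_mat, a_lab, sig)
pre, post, switched = generate_paired_switch(
    ExpressionSimConfig(n_genes=300, n_csm_samples=4, n_nse_samples=14,
                        noise_sd=0.25, seed=7), switch_fraction=0.5)
traced = trace_plasticity(score_matrix(pre, cent), score_matrix(post, cent))
n_nse = (traced.pre_call == "NS/E").sum()
conv  = ((traced.pre_call == "NS/E") & (traced.post_call == "CS/M")).sum()
print(f"{conv} of {n_nse} pre-treatment NS/E tumors converted to CS/M")
```

prints

```
signature: 15 genes (8 up, 7 down in CS/M)
6 of 14 pre-treatment NS/E tumors converted to CS/M
```

i.e. the derivation recovers exactly the planted 15-gene signature, and with
half the cohort switching state under treatment, 6 of the 14 initially
epithelial tumors are called mesenchymal afterwards — the pattern expected
when therapy enriches the resistant stem-like state.

A thin CLI mirrors the library: `cncl derive`, `cncl classify`, `cncl score`,
`cncl drugfit`, `cncl survival`, `cncl io convert|collapse`.

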