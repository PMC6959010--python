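# Methods

## The two-state model

The package assumes breast-cancer samples (cell lines, primary cells, bulk
tumors) occupy a spectrum between two transcriptional states: stem-like and
mesenchymal (CS/M) versus non-stem and epithelial (NS/E). The interface to
that spectrum is a small directional gene signature — a set of genes elevated
in CS/M (the "up" arm) and a set elevated in NS/E (the "down" arm) — used
three ways: to cluster samples into categorical states, to place each sample
on a continuous score, and to connect state to drug response and outcome.

All expression inputs are assumed normalized and on a log2 scale; FPKM data
are brought to log2(FPKM + 1) first, since the correlation-based score needs
comparable scales across genes. Missing values in the signature submatrix
are an error, not silently dropped: a Pearson correlation over ~15 genes
cannot absorb gaps.

## Signature derivation

Per dataset, each gene gets a Welch (unequal-variance) t-test between the
labeled groups. Degenerate inputs follow a fixed convention: both groups
constant with equal means → p = 1; constant with unequal means → p is the
smallest positive double. Genes at p < `initial_p` (default 0.05) are ranked
by p ascending (fold-change ordering is available; the ordering key is a
genuine free choice and p is the convention adopted) and cut to `top_n`
(default 200). Fold change is geometric: 2^|Δmean| of the log2 group means.

The two datasets' lists are intersected keeping only genes whose direction
agrees; then both-dataset filters fold ≥ `min_fold` (default 3) and
p < `max_p` (default 2×10⁻⁴) apply. The thresholds are applied per dataset
(both must pass) rather than on pooled statistics — the stricter and more
reproducible reading. Finally each candidate must show mean absolute
pairwise Pearson correlation ≥ `min_intercorr` (default 0.5) with the other
same-direction candidates, in both datasets. This filter is a single
non-iterative pass over the fold/p-passing set (a fixed point would depend
on removal order); singleton arms pass vacuously.

An empty result at any stage raises a typed error rather than returning an
empty list, because downstream stages would otherwise fail obscurely.

## Classification

Samples are clustered on the signature genes after per-gene z-scoring
(z-scoring is the default because cluster geometry should not be dominated
by high-variance genes; a center-only mode exists). Distances are Euclidean
with complete linkage, cut into k flat clusters. Cluster naming uses
polarity: mean z of up-arm genes minus mean z of down-arm genes, averaged
per cluster; highest polarity is CS/M, lowest NS/E, and with k = 3 the
middle cluster is intermediary (I). An exact polarity tie is an error — the
input carries no label information. The intermediary state can come either
from a k = 3 cut or from a score band (below); both routes are explicit
options because neither is canonical.

The cross-platform audit counts each (sample, dataset) call for samples seen
in ≥ 2 datasets as an assignment; a sample is inconsistent when its non-I
labels disagree, and is reported once however many datasets disagree.

## Stemness score

Reference centroids are per-gene medians of the z-scored signature
submatrix within each labeled group. "Standardization" is implemented as a
full z-score (center and scale); medians of differently scaled genes are not
comparable inside one correlation, which is why center-only is offered but
not default. Each sample's z-scored signature vector is Pearson-correlated
with both centroids; the score is Δr = r_CS/M − r_NS/E, bounded in [−2, 2]
(asserted). Test cohorts are standardized against their own gene means by
default; an analysis can instead reuse reference standardization by scoring
pre-standardized vectors directly.

Categorical calls: Δr > cutoff + band → CS/M; Δr ≤ cutoff − band → NS/E;
inside the band → I. The default cutoff is 0 (a negative score means more
epithelial); a boundary value goes to NS/E, a deliberate tie-break so that
only strictly positive margins claim the stem-like label. Cohort-specific
cutoffs come from the LRMC scan.

Plasticity tracing joins paired pre/post score tables and flags a switch
when the two calls are distinct non-I labels; pairs touching I are not
counted as switches by default since an intermediary call is evidence of
position, not of transition.

## Dose-response ensemble

Viability (% of control) versus dose is fit with the 4-parameter logistic
v(d) = bottom + (top − bottom)/(1 + (d/ic50)^hill) under six constraint
patterns: {hill free, hill = 1} × {unconstrained, top = 100, bottom = 0}.
The "3-parameter" family is the hill = 1 branch; the naming counts curve
parameters, so "4 parameter Top 100" has three free parameters. Fitting is
trust-region least squares on log10 dose with bounds (bottom ∈ [−50, 150],
top ∈ [−50, 200], log10 IC50 within ±4 decades of the tested range,
hill ∈ [0.05, 20]), initialized at bottom = min(v), top = max(v), IC50 at
the dose nearest the half-range crossing, with a 3-point multi-start over
hill ∈ {0.5, 1, 2} for the hill-free models.

Model selection minimizes the residual standard error sqrt(RSS/(n − p)),
which penalizes free-parameter count and makes the six models comparable.
IC50 is the curve midpoint (relative IC50); a fitted midpoint beyond the
highest tested dose, or a dose-independent flat curve, is reported as
right-censored ("> max dose"). Activity area is the mean per-dose inhibition
max(0, 1 − v/100) ∈ [0, 1]; a trapezoid-on-log-dose variant is provided.
Noise in the simulator is additive Gaussian on the percent scale, truncated
to [−10, 130]% to mimic out-of-range assay readings.

**Precision limit.** With a 10-point half-log dose series, quadruplicates
and 2% viability noise, the midpoint of ordinary curves (hill ≥ 1) is
recovered within ~3% (median over a seed batch). Shallow curves (hill = 0.5)
spread their transition over many decades, leaving the asymptotes — and
hence the midpoint — weakly identified: median recovery error there is
~5–9% and single realizations can err by 20–30%. This is an information
limit of the design, not of the fitter: the fits match an independent
grid-plus-polish oracle to within tolerance. Screens relying on absolute
IC50s of shallow curves should use the activity area instead, which remains
stable.

## Survival

The log-rank test and Cox regression delegate to lifelines (tests cross-check
the log-rank against the hypergeometric formula). The LRMC scan dichotomizes
Δr at its 10th–90th percentiles in steps of 5, discards cutoffs leaving
either group below 10% of the cohort, and reports the minimum-p cutoff.
Because scanning is anti-conservative (the null distribution of the minimum
p is not uniform — a demonstration test shows >10% of null cohorts reach
nominal p < 0.05), the scan can attach a permutation-adjusted p: scores are
permuted against (time, event), the scan repeated, and the adjusted p is the
fraction of permutations at least as extreme (never reported below the naive
minimum). Both numbers are reported side by side. Whether a published
cutoff was optimized or pre-chosen is usually unknowable; the scan makes the
optimization explicit and quantifies its cost.

Cox covariates may be numeric or categorical (one-hot, first level as
reference). Non-convergence (e.g. separation) surfaces as a typed error.

## Synthetic data: what it does and does not emulate

The expression generator plants a directional signature on a log2-Gaussian
background: gene baselines ~ N(8, 1), group shifts of ±effect/2, noise sd
default 0.5 on the log2 scale, and a shared per-arm latent factor (weight
0.7) so signature-arm genes co-vary as real stemness/EMT genes do (pairwise
r ≈ weight²). Defaults — 8 up/7 down planted genes, 20 + 20 samples,
log2 effect 3 (so planted genes clear a 3-fold filter with margin) — mirror
the regime in which a 15-gene two-state signature is derivable from
cell-line panels; the effect size and noise are calibration choices, since
no empirical figures exist for them. Not modelled: probe-level physics,
batch effects, RNA-seq count overdispersion, or correlation between the two
arms beyond what the group structure induces. Passing tests therefore show
the pipeline's operations are correct and recover planted structure; they do
not show that any particular real cohort separates cleanly.

Paired cohorts redraw post-treatment samples from their own or the opposite
group's generative model (switched samples chosen uniformly at random).
Survival is two-group exponential with proportional hazards and independent
exponential censoring — the cleanest regime in which log-rank/Cox recovery
can be checked against the planted hazard ratio.

## Problem sizes

Tests and the acceptance script run on deliberately small instances chosen
to make every planted quantity recoverable with margin: 200–300-gene
universes, 20 + 20-sample cohorts, 41-sample three-platform audits, an
18-tumor paired design (14 NS/E + 4 CS/M, mirroring the classic
pre/post-endocrine-therapy layout), 5-seed batches per dose-response grid
cell, 200-replicate null studies for type-I error, and 300–400-subject
survival cohorts.
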