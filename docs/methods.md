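# Methods

## Pseudobulk views

Per (sample, cell type), UMI counts are summed over member cells; profiles
from fewer than `min_cells = 25` cells are discarded. Gene QC keeps a gene
iff its maximum count across samples is ≥ `min_count = 100` **and** it is
detected (count > 0) in at least `min_detection = 25%` of samples — a gene
detected in exactly 25% of samples is kept. The rule is idempotent.

Normalisation is trimmed-mean-of-M-values (TMM): the reference sample is
the one whose 75th percentile of library-scaled counts is closest to the
mean of those percentiles; per sample, M (log2 depth-scaled ratio) and A
(average log abundance) are computed over genes positive in both
libraries, double-trimmed two-sided at 30% (M) and 5% (A) using 1-based
ordinal ranks, and averaged with inverse-approximate-variance weights
`(N−y)/(Ny)` summed over the two libraries. Factors are rescaled to
geometric mean 1 and expression reported as
`log2(1e6·y/(lib·factor) + prior_count)` with `prior_count = 1`.

Highly variable genes come from a mean–variance trend on log-CPM: lowess
with span 0.3 (quadratic polynomial below 30 genes), trend floored at
1e-12. `normvar` keeps variance/trend > 1.5; `biovar` keeps
variance − trend > 0 (the default).

Cell-type markers use one-vs-rest Welch t-tests on log-CPM pseudobulks
(lfc > 1, BH FDR < 0.01). This is a deliberate simplification: the
negative-binomial quasi-likelihood machinery usually used for pseudobulk
differential expression is out of scope here, and the background filter
only needs high-confidence markers, which any reasonable test agrees on.
Cell-state markers are one-vs-rest t-tests within a cell type on
log1p-CP10K cells (lfc ≥ 0.5, adjusted p < 0.05).

Background exclusion: for cell type *c*, the final gene set is
`hvg(c) \ (∪_{c'≠c} markers(c') \ markers(c))` — highly variable genes
that could mark another cell type are treated as putative ambient-RNA
contamination and removed, but a type's own markers are exempt. The
output is always a subset of the input and empty markers give the
identity.

View assembly centres every feature per group. With more than one group
(meta-analysis across studies) each feature is additionally scaled to unit
variance per group (population SD); features with zero variance in a group
are dropped from that group's likelihood (NaN-masked), never zero-filled.
Single-group data are centred only. Structural views: compositions are
closed to 1, zeros replaced multiplicatively by half the smallest positive
part of the row (re-closed), and CLR-transformed; spatial-dependency views
keep the `top_n = 21` interaction columns with the highest variance of the
supplied standardised importances.

## Group factor analysis

Generative model and priors are given in the README. Inference is
mean-field coordinate ascent: Gaussian updates for each row of Z (per
sample, full K×K covariance) and of W (per feature), Gamma updates for
α (per view × factor), β (per group × factor, fixed at 1 for one group so
scores keep a standard-normal prior), and τ (per view × group × feature —
noise levels differ between studies). Missing entries, including samples
that lack a view entirely, are excluded from every sufficient statistic
and from the ELBO, which makes the bound exact for observed data and
monotone under the updates; perturbing masked entries provably leaves the
fit bitwise unchanged.

Defaults: all Gamma shapes/rates 1e-3 (uninformative), `tol = 1e-6`
relative ELBO change, `max_iter = 1000`, `seed = 1`, `K = 6`. K is fixed
by the user; ARD shrinks unneeded factors instead of dropping them, and
factors with overall explained variance below 0.5% can be flagged
inactive post hoc. Initialisation: Z ~ N(0,1) from the seeded generator,
W at zero, precisions at their prior means. Because a Z-update against an
all-zero W would collapse q(Z) to its prior, the first sweep starts at
the W update (consuming the random Z); from the second sweep the order is
Z, W, α, β, τ, ELBO. Every update is exact CAVI, so the ELBO is monotone
from the first evaluation. Convergence on near-degenerate problems
(duplicate factors under ARD shrinkage) is slow; recovery experiments use
`max_iter` up to 4000 with `tol = 1e-9`. Coordinate ascent can also stall
in clearly inferior local optima where one factor splits in two;
`n_restarts` refits from consecutive seeds and keeps the restart with the
highest final ELBO (gross failures sit visibly below the good optima on
the ELBO scale), while remaining fully deterministic.

Explained variance per (view, group, factor) is
`1 − Σ_obs (y − E[z_k]E[w_k]^T)² / Σ_obs y²`; totals use the full
reconstruction. Raw values are reported (single-factor r² can be negative
when factors correlate). Post-processing orders factors by decreasing
overall r² and flips each factor's sign so the weight skewness
(Σ w³) is positive in the view where the factor explains most variance;
the reconstruction is invariant and the operation idempotent.

## Interpretation

Factor–covariate association: tie-corrected Kruskal–Wallis for
categorical covariates (χ² p, df = levels − 1), univariate linear-model
F-test for continuous ones; BH across factors within each covariate.

Signatures: per cell type, loadings with |w| < 0.1 are zeroed; survivors
form a positive and a negative signature. Their interpretation depends on
the factor's association direction, which is left to the caller.

Weighted-mean scoring: raw score `s = Σ x_g w_g / Σ |w_g|`; the null
draws `|S|` genes uniformly without replacement from the measured
universe and reassigns the signature's weights in fixed order
(gene-identity permutation, not sample permutation), `z = (s − μ₀)/σ₀`
with the sample SD of the null (ddof 1). A zero null SD yields z = 0 with
a degeneracy flag rather than an error, since constant spots occur in
sparse spatial data. Defaults: 1000 permutations for functional scoring,
100 for spatial and bulk. The permutation index stream depends only on
(seed, signature size, universe size), so scoring one sample alone or in
a batch is bitwise identical.

Cell-state enrichment: upper-tail hypergeometric `P(X ≥ k)` of marker
sets in signature genes, BH across states within a cell type, positive
and negative signatures tested separately. Variance partition: per gene,
one-way ANOVA η² for condition-labelled and state-labelled pseudobulks;
BH within each grouping at α = 0.01; `r = log2(η²_cond / η²_state)` for
genes with both η² > 0 (others counted and excluded); per cell type a
one-sample t-test of r against 0 plus a Shapiro–Wilk p on r — both are
reported, neither gates results.

## Spatial mapping and transfer

Spot scoring applies the weighted mean per spot over the slide's own gene
universe; spots where the signature's cell type has proportion < 0.1 are
masked (NaN, never 0 — 0 is a meaningful z). The effective area is the
number of spots with proportion ≥ 0.1; active spots have z strictly
greater than 2 (boundary spots count inactive); the relative activation
area is their ratio, compared across conditions with two-sided rank-sum
tests, BH within each condition pair.

Projection: new cohorts are processed with the same pipeline and centred
with their own per-feature means (each study is processed independently;
this shifts projected score offsets but preserves geometry). Weights and
data are restricted to shared (view, gene) pairs — exact symbol matching,
no ortholog resolution — and `Z = (W⁺ Y)ᵀ` per missingness pattern; a
rank-deficient W yields the minimal-norm solution with a flag. Bulk
studies are z-scored per gene within the study (never pooled) before
scoring; signatures with < 10% of genes measured are skipped. Silhouette
widths use Euclidean distances, 0 for singleton labels and degenerate
0/0 cases. Downstream classification of projected scores is deliberately
out of scope — any classifier can consume the projection result.

## Synthetic data

The generators emulate the structure of cross-condition atlases, not
their biology.

- `simulate_multiview` draws directly from the generative model. The
  default activity pattern gives every factor a distinct subset of active
  views (factor 1 everywhere, later factors each silencing different
  views). This mirrors real multicellular programs, which involve
  different cell-type subsets, and it makes factors identifiable up to
  sign — with identical activity everywhere the likelihood is
  rotation-invariant and per-factor recovery would be ill-posed. Default
  noise SD 0.3 against unit-variance factors.
- `simulate_single_cell`: 3 cell types × 2 states, 300 genes, 10 samples
  per condition × 2 conditions, 80 cells per (sample, type), log-normal
  depths (median 2500, σ 0.35). Counts are
  Multinomial(depth, (1−λ)·π + λ·π_ambient) with λ = 0.1 by default and
  π_ambient the sample's cell-weighted mean profile. Planted: 10
  exclusive markers per type (structural zeros elsewhere at λ = 0), 5
  markers per state (×4), and a multicellular program of 10 up + 10 down
  genes whose rates shift ×3 / ÷3 in every cell type of case samples.
  Per-sample log-normal rate jitter (σ 0.15) provides sample-level
  variability beyond the condition. Planted genes draw their baselines
  from the upper part of the expression distribution — programs and
  markers in real atlases are defined over detectable genes, not the
  noise floor. The ambient pool is a single per-sample profile; there are
  no doublets and no dropout beyond multinomial sampling.
- `simulate_slides`: 12×12 spot grids, Dirichlet proportions with the
  target type favoured in one half (two niches), i.i.d. Normal baseline
  expression, and in case slides a +1.5/−1.5 shift of the program genes
  in 40% of the spots where the target type is present.
- `simulate_bulk_cohort`: linear expression as the composition-weighted
  mixture of log-normal cell-type profiles, program genes ×2 / ÷2 in case
  samples, log-normal noise; composition priors identical across
  conditions by default so only the program separates groups.

Problem sizes are deliberately modest (hundreds of genes, tens of
samples) so the full pipeline runs in seconds; passing tests demonstrate
correctness of the computations and recovery under the stated generative
assumptions, not performance on real atlases with batch effects,
annotation errors or non-Gaussian expression.

## Numerical choices and limitations

- TMM trimming uses ordinal ranks (ties broken by position); samples
  identical to the reference get factor 1 exactly.
- The `normvar` HVG statistic is a variance/trend ratio; parity with any
  particular external implementation of trend fitting is not guaranteed.
- Kruskal–Wallis is rank-based, hence invariant under strictly monotone
  transforms of the scores.
- Activation `z > 2` is strict; "greater than two" boundary spots are
  inactive.
- Single-factor r² values are raw (possibly negative); display clipping
  is the caller's choice.
- ELBO monotonicity is guaranteed by construction but convergence near
  rotation-degenerate optima is slow; duplicated factors decay gradually
  under ARD rather than being dropped.
- BH families are explicit: factors within covariate; states within
  (cell type, sign); genes within (cell type, grouping); (cell type,
  sign) within condition pair.
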