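# Methods

`cwfkit` estimates **cell type-specific weighting factors (cWFs)** —
non-negative per-cell coefficients that restore the transcriptome-size
information erased by per-cell normalization of scRNA-seq data — and
uses them for reconstitution of bulk profiles, Bayesian deconvolution,
and condition (aging-stage) classification. This note records the model,
the numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## The weighting-factor model

Bulk RNA-seq of a solid organ is, to first order, the mixture of its
composite cell types weighted by abundance *and* by per-cell mRNA
content (transcriptome size). CPM normalization of scRNA-seq equalizes
every cell's total to 10^6, so a plain ratio-weighted sum of
single-cell profiles misstates the contribution of large or small cell
types. The cWF of cell *j* is the coefficient `w_j >= 0` in

    m * y_i ≈ Σ_j w_j x_j ,   j ∈ C^m,

where `y_i` is a CPM bulk replicate, `x_j` a CPM single-cell profile
restricted to the signature genes, and `C^m` a random combination of
`m` cells drawn so that per-type counts follow the reference cell-type
ratios (largest-remainder apportionment with a floor of one cell per
type). Each round solves

    argmin_{w >= 0} Σ_i || m y_i − Σ_j w_j x_j ||²,

a non-negative least-squares problem (Lawson–Hanson via
`scipy.optimize.nnls`; summing the squared residuals over replicates is
algebraically a single NNLS against `m` times the replicate mean).
Rounds repeat until every cell in the pool has accumulated more than
`min_samples` (default 100) factors. To guarantee termination in a
bounded number of rounds, draws within each type are biased toward the
least-covered cells (uniform draws are available through
`sample_subject_combination` directly). Per-cell summaries use the
unbiased (n−1) variance, since downstream Gaussian priors consume them
at modest sample counts.

The `m`-multiplication on the left-hand side is kept exactly as the
model states. Its compensation for combination size is imperfect —
per-type mean cWFs drift slightly with `m` — but relative orderings
across types are stable (tested for m ∈ {15, 30, 60}).

cWFs are **relative** quantities: comparable across cell types within
one organ/bulk dataset, not across datasets or conditions. Cross-
condition comparisons therefore use pairwise ratios (below).

## Signature genes

Cell types are discriminated by a random forest (500 trees) on the
CPM-normalized single-cell matrix, split 80:20 stratified by type. The
per-split feature count is tuned by a stepwise doubling search around
sqrt(#genes) on out-of-bag error (step factor 2, relative improvement
threshold 5%). Genes are ranked by Mean Decrease in Gini (sklearn's
impurity importance); ties break lexicographically so rankings are
reproducible. A held-out macro-F1 ≤ 0.8 flags the signature set without
suppressing it. Macro averaging was chosen because per-organ type
frequencies are strongly imbalanced. Different signature sizes are
truncations of one fitted ranking (top-100 is a prefix of top-300), not
refits.

## Bayesian deconvolution

With per-cell summaries `(μ_wj, σ²_wj)`, each type `k` (with `N_k`
cells) receives a diagonal Gaussian prior over its cWF-weighted profile:

    μ'_k = (1/N_k) Σ_j μ_wj x_j ,
    S_k  = (1/N_k) Σ_j σ²_wj (x_j ⊙ x_j).

The generative model for a bulk vector `y` is

    y | X, r ~ N(Xr, βI),  x̄_k ~ N(μ'_k, S_k),  r ~ Dirichlet(α·1_K),

with half-normal(0,1) hyperpriors on α and β. Sampling is restricted to
the signature genes.

**Variance convention.** The stored prior diagonal divides the summed
per-cell variances by `N_k` once ("pooled", the default), which leaves
its relative width independent of `N_k` (≈100% relative sd in
practice). `build_type_priors(..., variance_convention="sem")` divides
by `N_k²` instead — the variance a mean of independent draws would have
— for sensitivity analysis. Under the pooled convention the marginal
likelihood's log-determinant term (an Occam penalty on high-variance
mixtures) can bias posterior ratios by ~0.05–0.1 on an otherwise
well-specified balanced mixture; this is a property of the stated
model, reported as-is.

**Sampler.** The posterior is explored with a No-U-Turn Sampler written
against analytic gradients (slice formulation, dual-averaging step-size
adaptation toward 0.9 acceptance, diagonal mass matrix re-estimated at
mid-warmup). Because likelihood and priors are Gaussian with diagonal
covariances, **X is marginalized in closed form** during sampling — the
chain moves only in `(r, α, β)` through an additive-log-ratio transform
of the simplex and log transforms of the positive scalars — and per
kept draw X is recovered exactly from its per-gene conditional Gaussian
(rank-one-corrected covariance, batched Cholesky). Negative sampled
elements of X are clamped to zero per draw before averaging into the
EAP. This targets the same joint posterior as sampling X directly but
mixes far better (the X block is ~K×#signature-genes dimensions of
near-deterministic conditionals). Genes whose prior variance is zero in
every type are held at their prior means. Convergence is gated at
split-Gelman-Rubin R-hat < 1.1 over all sampled variables (r, α, β);
the split-R-hat implementation is cross-checked against `arviz` in the
test suite. Chains default to 4 × (1000 warmup + 1000 kept), target
acceptance 0.9, max tree depth 12; tests and the acceptance script use
2 × (500 + 500), which converges comfortably on K ≤ 4 problems.

**Non-signature genes.** With ratios fixed at their posterior mean,
each remaining gene's per-type counts are filled in by the analytic
conditional update

    E[x̄_k] = (γ r_k² I + P_k)⁻¹ (γ r_k y + P_k μ'_k − γ Σ_{l≠k} r_k r_l x̄_l),

iterated Jacobi-style over all types from `x̄ = μ'` until the
inter-iteration RMSE falls below 1 (CPM scale; configurable because it
is scale-dependent) or 100 passes. Negative values are zeroed in the
result. γ is chosen from the decade grid 10^-5 … 10^5 by least RMSE
between `y` and the remixed estimate `Σ_k r_k E[x̄_k]`.

**A deliberate notational tension.** The prior diagonal `S_k` enters
the sampling prior as a *variance* but the analytic update above in the
*precision* slot (`P_k`); only the precision reading makes the update
the conjugate conditional mean, which the test suite verifies against
brute-force Monte-Carlo conditional means. Both readings are exposed
rather than silently reconciled, and the recorded posterior "variance"
`γ r_k² + P_k` is stored in the same printed form.

**Known failure mode.** A symmetric Dirichlet prior is a poor match for
organs dominated by one transcript-rich cell type (a liver-like 95%
composition): the minor types contribute a few percent of bulk
transcripts, the likelihood barely constrains their ratios, and the
prior pull inflates them. The acceptance suite reproduces this as a
higher ratio-RMSE for a dominant-type fixture than for a balanced one
under identical settings.

## Reconstitution scoring

Per estimation round, the synthetic bulk with cWFs (`Σ w_j x_j`) and
without (`Σ x_j`) is correlated (Pearson) against each bulk replicate
on the signature genes. Pearson is scale-invariant, so no
renormalization is applied. With all `w_j = 1` the two syntheses are
identical by construction.

## Aging analysis

For a type pair (X, Y) at one condition, the ratio distribution is the
full cross product `w_X / w_Y`; zeros are first replaced by the list's
second-smallest value to avoid division by zero. Stage differences are
tested per pair with two-sided Mann-Whitney U tests (tie-corrected
normal approximation above exact-test sizes, i.e. scipy's default);
p-values below 1e-308 are reported as exactly 0, and pairs with p <
0.01 in any stage comparison are kept. Note the cross product
pseudo-replicates — n·m dependent ratios from n+m cells — so U-test
p-values overstate evidence at large n; planted-shift fixtures are
therefore asserted on effect ordering, not on non-significance of null
pairs.

The classifier input per stage is a matrix of 100 values drawn
independently per surviving pair (with replacement when a distribution
is smaller), deliberately destroying cross-pair correlation. A LightGBM
multiclass model is tuned by seeded random search over max_depth 3–12,
num_leaves 2–256, subsample 0.1–1.0, subsample_freq 1–7,
colsample_bytree 0.1–1.0, min_child_samples 5–100, maximizing macro-F1
on a validation split of the 80% training split, then refit and scored
on the held-out 20%. Feature importances use LightGBM gain.

The reported `accuracy` is the **mean per-stage binary accuracy**
`(1/K) Σ_a (TP_a+TN_a)/n` — which differs from conventional multiclass
accuracy; the conventional quantity is reported alongside as
`overall_accuracy`. Zero-denominator metric components are defined as 0
with a warning. The formulas generalize from 3 stages to K by replacing
1/3 with 1/K.

## Synthetic data

`simulate_dataset` plants, per type: a CPM profile with a marker block
(default 10 genes at 20-fold enrichment, 0.05-fold elsewhere), a
relative transcriptome size `s_k`, and an abundance on the simplex.
Cells are Poisson (optionally negative-binomial, gamma-Poisson mixture)
draws at depth `base_depth · s_k` (default 20,000 counts — a realistic
droplet-protocol depth), then CPM-normalized so size information
survives only in the bulk. Bulk replicates are
`Σ_k ratio_k s_k profile_k` under multiplicative log-normal noise of a
given CV, CPM-normalized; with zero noise the bulk equals the weighted
mixture exactly. Optional "cryptic" genes are expressed in the
dissociated single cells but absent from bulk, emulating
dissociation-induced expression. `simulate_stage_cwfs` generates
per-stage log-normal cWF samples with one type's log-mean drifting
across stages — the planted aging signal.

What the generator does **not** emulate: dropout/zero inflation beyond
the count model, batch effects, ambient RNA, doublets, within-type
substructure, or any real organ's expression landscape. Passing tests
demonstrate the estimators' correctness under the stated generative
assumptions, not performance on real atlas data.

## Problem sizes and defaults used in tests

Fixtures are deliberately desk-scale: 3–4 types, 120–300 genes, 40–200
cells per type, m ∈ {15–40}, signature sizes 15–50, samplers at 2
chains × 500 draws. The size-recovery fixture (4 types, sizes 1/2/4/8,
200 cells/type, 50 signature genes, m = 40, noiseless bulk) recovers
size ratios to well under 1% relative error; the Bayesian ratio
recovery over 10 random simplex points with correct truth-derived
priors (5% relative sd) achieves mean RMSE < 0.01 with all R-hat < 1.1.
Reported degradations (pooled-variance priors, dominant-type organs)
are measured by the same scripts.

## Degenerate inputs and tie-breaks

- Zero-total cells fail CPM normalization loudly (no silent dropping).
- Gene subsetting clears the CPM flag (subvectors no longer sum to 10^6).
- Equal Gini importances break lexicographically; apportionment
  remainders break by larger fraction, then larger ratio, then label
  order; a forced one-cell floor takes its slot from the largest quota.
- NNLS outputs in [−1e-9, 0) are clamped to 0; anything more negative
  is an error.
- `K = 1` deconvolution returns `r = (1.0)` without sampling.
- The analytic update guards `γ r_k² + P = 0` coordinates by returning
  the prior mean.
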