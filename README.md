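# cwfkit

Cell type-specific weighting factors for reconciling bulk RNA-seq with
its composite single-cell data.

## The problem

scRNA-seq of solid organs normalizes every cell's transcript counts to
a common total (CPM), which erases per-cell **transcriptome size** —
the total mRNA content, which varies several-fold between cell types —
and is further distorted by dissociation-induced cryptic expression. As
a result, summing single-cell profiles at the known cell-type ratios
fails to reconstitute the organ's bulk RNA-seq profile, and
reference-based deconvolution inherits the same bias.

`cwfkit` is for computational biologists who have matched bulk and
single-cell RNA-seq of the same tissue and want to (a) quantify each
cell type's relative transcriptome size, (b) deconvolve bulk profiles
into cell-type ratios and per-type "virtual transcriptomes" with that
size bias corrected, and (c) compare how these factors shift across
conditions such as aging stages.

## The method

A **cell type-specific weighting factor (cWF)** is the non-negative
per-cell coefficient `w_j` in

    m·y ≈ Σ_j w_j x_j ,   w_j ≥ 0,   j ∈ C^m,

where `y` is a CPM bulk profile, `x_j` the CPM profile of cell `j`,
and `C^m` a random combination of `m` cells honoring the reference
cell-type ratios. Each round solves this non-negative least-squares
problem on the organ's signature genes (top-*n* random-forest Gini
ranking); rounds repeat until every cell has >100 sampled factors,
whose per-cell Gaussian summaries `(μ_wj, σ²_wj)` proxy relative
transcriptome size.

Deconvolution then treats the bulk vector as `y = Xr + ε`,
`ε ~ N(0, βI)`, with per-type priors `x̄_k ~ N(μ'_k, S_k)` built from
the cWF summaries and `r ~ Dirichlet(α·1_K)`; the posterior over
ratios and virtual per-type profiles is explored with a No-U-Turn
sampler (R-hat < 1.1 convergence gate), and non-signature genes are
completed by an analytic conditional update with a grid-selected
hyperparameter γ. Cross-condition analysis works on pairwise cWF
ratios: Mann-Whitney U tests gate the informative type pairs and a
tuned LightGBM classifier predicts the condition (aging stage) from
them. See `docs/methods.md` for the full model and numerical choices.

## Worked example

Synthetic organ, three cell types with transcriptome sizes 1 : 2.5 : 5
mixed at ratios 0.5 / 0.3 / 0.2 — everything below is computed, none of
it is read from the ground truth:

```python
import numpy as np
from cwfkit import (
    ReferenceRatios, SamplerConfig, build_type_priors, deconvolve,
    estimate_cwfs, reconstitution_report, select_signature_genes,
    SimulationConfig, simulate_dataset, summarize_per_type,
)

cfg = SimulationConfig(
    n_types=3, n_genes=200, cells_per_type=(150, 150, 150),
    true_sizes=(1.0, 2.5, 5.0), true_ratios=(0.5, 0.3, 0.2),
    noise_cv=0.02, seed=11,
)
sc, annotation, bulk, truth = simulate_dataset(cfg)
ratios = ReferenceRatios(truth.ratios)

signature = select_signature_genes(sc, annotation, 20, split_seed=11, tune=False)
print(f"signature macro-F1: {signature.classifier_f1:.3f}")

cwfs = estimate_cwfs(bulk, sc, annotation, ratios, signature,
                     m=30, min_samples=100, rng_seed=11)
for cell_type, stats in sorted(summarize_per_type(cwfs).items()):
    print(f"{cell_type}: mean cWF {stats['mean']:.3f}  (n={stats['n']})")

report = reconstitution_report(bulk, sc, annotation, ratios, signature,
                               n_recursions=20, m=30, rng_seed=11)
print(f"median Pearson r: {report.r_with_cwf.median():.4f} with cWFs, "
      f"{report.r_without_cwf.median():.4f} without")

priors = build_type_priors(sc, annotation, cwfs)
result = deconvolve(bulk.values.mean(axis=1), bulk.gene_ids, priors, signature,
                    SamplerConfig(n_chains=2, n_warmup=500, n_samples=500, seed=11))
for cell_type in result.cell_types:
    print(f"{cell_type}: estimated ratio {result.ratios[cell_type]:.3f} "
          f"(true {truth.ratios[cell_type]:.3f})")
print(f"max R-hat {result.rhat_max:.3f}, gamma {result.gamma_selected:g}")
```

Output:

```
signature macro-F1: 1.000
type0: mean cWF 0.443  (n=37875)
type1: mean cWF 1.118  (n=22725)
type2: mean cWF 2.214  (n=15150)
median Pearson r: 0.9998 with cWFs, 0.9033 without
type0: estimated ratio 0.508 (true 0.500)
type1: estimated ratio 0.322 (true 0.300)
type2: estimated ratio 0.170 (true 0.200)
max R-hat 1.002, gamma 100000
```

The recovered mean cWFs stand in the planted 1 : 2.5 : 5 proportion
(0.443 : 1.118 : 2.214), the weighted synthesis closes the
reconstitution gap (0.90 → 0.9998 median Pearson), and the posterior
ratios land within a few percent of the true composition with
converged chains.

The same stages are available from the shell:

```bash
cwfkit simulate --seed 11 --out fixture/
cwfkit signatures --counts fixture/sc_counts.csv --labels fixture/ann.csv \
       --n 20 --seed 11 --out sig.csv
cwfkit run --config pipeline.yaml          # YAML-configured end-to-end run
```

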