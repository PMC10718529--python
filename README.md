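# mcfa — multicellular factor analysis

`mcfa` analyses cross-condition single-cell atlases at the *sample* level.
Instead of asking which genes change in one cell type, it asks which
**multicellular programs** — coordinated gene-expression changes across
several cell types — distinguish patient samples, and it provides the
downstream machinery to interpret, map and transfer those programs.

It is aimed at computational biologists working with multi-sample
single-cell (or single-nucleus) RNA-seq cohorts, optionally alongside
spatial transcriptomics slides and bulk transcriptomics studies.

## The model

Per cell type *m*, UMI counts are summed into pseudobulk profiles per
sample, filtered, TMM-normalised to log-CPM, reduced to highly variable
genes and cleaned of likely ambient-RNA contaminants. Each cell type
becomes one **view**: a samples × genes matrix `Y^{m,g}` (optionally per
cohort *group* `g`). The views are decomposed jointly by a group factor
analysis,

```
y[n,d] = Σ_k  z[n,k] · w[d,k] + ε,          ε ~ N(0, 1/τ[m,g,d])
w[d,k] ~ N(0, 1/α[m,k]),   α[m,k] ~ Gamma(a0, b0)
z[n,k] ~ N(0, 1/β[g,k]),   β[g,k] ~ Gamma(c0, d0)
```

fitted by mean-field variational Bayes with closed-form coordinate
updates. The automatic-relevance-determination precisions `α` (per view ×
factor) and `β` (per group × factor; fixed to 1 for a single group) let a
factor switch off in cell types or cohorts where it is not needed, samples
may miss entire views (masked, never imputed), and features need not
overlap between views. Factor scores `z` are per-sample coordinates in the
multicellular latent space; weights `w` say how much each gene of each
cell type contributes.

Downstream, the package: associates factors with sample covariates
(Kruskal–Wallis / linear model, BH-corrected); extracts per-cell-type
**factor signatures** (loadings with |w| ≥ 0.1, split by sign); scores
signatures on any expression matrix with a permutation-normalised weighted
mean; maps them onto spatial slides and summarises **relative activation
areas**; adds compositional (CLR) and spatial-dependency views; projects
new cohorts into a reference latent space via the Moore–Penrose
pseudoinverse; and scores signatures across bulk studies with
silhouette-based evaluation.

## Worked example

Everything below runs on synthetic data with planted ground truth — no
downloads needed:

```python
from mcfa import (simulate_single_cell, build_pseudobulk, qc_filter_genes,
                  tmm_normalize, select_hvg, detect_markers,
                  exclude_background, assemble_views, fit_gfa,
                  postprocess_factors, GFAHyperparams, associate_factors,
                  extract_signatures)

cells, truth = simulate_single_cell(seed=0)          # 3 cell types, 20 samples
pb = build_pseudobulk(cells, min_cells=25)
views = {ct: tmm_normalize(qc_filter_genes(v)) for ct, v in pb.items()}
hvg = {ct: select_hvg(v) for ct, v in views.items()}
markers = detect_markers(views)
gene_sets = exclude_background(hvg, markers)
data = assemble_views(views, gene_sets=gene_sets)

model = postprocess_factors(fit_gfa(data, GFAHyperparams(K=6, seed=1)))
assoc = associate_factors(model.scores(), truth.condition.to_frame("condition"))
print(assoc.sort_values("padj").head(1))
```

which prints (Factor1 is the planted disease program):

```
    factor  covariate         kind  statistic      pval      padj
0  Factor1  condition  categorical  14.285714  0.000157  0.000942
```

`extract_signatures(model, 0)` then yields the per-cell-type gene
signatures of that factor; on this data they recover 100% of the planted
program genes with the correct sign.

The same workflow is available from the shell:

```bash
mcfa simulate --kind single_cell --seed 0 --out fixture/
mcfa run --seed 11 --out artifacts/
```

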