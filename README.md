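# ontomodules

Coexpression-module discovery and molecular-evolution profiling for
developmental transcriptome time series.

## The problem

Over the course of development — from a one-cell embryo to a reproducing
adult — every gene traces out an expression trajectory. Genes whose
trajectories share a shape ("coexpression modules") tend to share function,
genomic neighbourhood and, strikingly, rates of protein evolution: in
*C. elegans*, genes peaking in early embryogenesis or toward adulthood
diverge fastest between species, while broadly expressed "constitutive"
genes are the most conserved. `ontomodules` is a tested, reusable pipeline
for this style of analysis. Starting from a gene × sample count table for an
ordered developmental series (e.g. 25 embryonic timepoints at 30-minute
intervals plus larval stages L1–L4 and young adult), it:

1. **Normalises** counts to log₂ counts-per-million
   (`log2((count + 0.5) / (library_size + 1) × 10⁶)`), averages replicates
   on the log scale, drops genes below 1 CPM at every timepoint, and
   recomputes log-CPM on the filtered counts.
2. **Decomposes** trajectories by functional PCA. On a dense regular grid
   this is the eigendecomposition of the T × T covariance of the
   gene-centred trajectory matrix; each gene gets scores on the leading
   eigenfunctions.
3. **Clusters** genes in the plane of the first two FPC scores with a
   full-covariance Gaussian mixture fitted by EM (k-means++ starts, 10
   restarts), choosing the number of modules k by minimising
   `BIC = −2 log L + p ln n` with `p = (k−1) + 2k + 3k`. Genes join the
   module with their highest posterior membership probability.
4. **Parameterises** each trajectory by an orthogonal cubic fit
   `y(t) ≈ α + β₁P₁(t) + β₂P₂(t) + β₃P₃(t)` on the time grid rescaled to
   [−1, 1]: α is the overall expression level (exactly the profile mean),
   β₁ the linear trend, β₂ the concave/convex curvature, β₃ the S-shape.
   Linear discriminant analysis on (α, β₁, β₂, β₃) validates that the four
   shape metrics capture module identity; hierarchical clustering of
   module-level coefficients relates modules to each other.
5. **Tests enrichment** of every module against chromosomes, arm/center
   recombination domains, operon membership, gamete expression classes
   (spermatogenic / oogenic / sex-neutral) and early-embryo categories
   (maternal / embryonic / transient / degradation) with 2×2 χ² tests
   (1 df), Holm–Bonferroni corrected for the genomic families and
   Bonferroni for the cross-referenced gene sets.
6. **Links dynamics to divergence** through per-module summaries of K_A
   (nonsynonymous substitutions per nonsynonymous site between orthologs),
   peak-expression timepoints mapped to developmental stages, stage-wise
   geometric-mean K_A, the transcriptome divergence index
   `TDI_t = Σᵢ wᵢₜ K_Aᵢ / Σᵢ wᵢₜ` with linear-scale expression weights,
   and an OLS regression of log K_A on the four shape metrics.

A fully seeded synthetic-data generator (`ontomodules.synthetic`) produces
desk-scale datasets with this exact statistical structure — cubic-shaped
module mean curves, Gaussian log-scale noise, module-dependent lognormal
K_A and categorical enrichments — so every stage is testable end to end
without external downloads.

## Worked example

Generate the default synthetic scenario (3,000 genes, 30 timepoints, 8
generating modules) and run the full pipeline:

```bash
ontomodules simulate --seed 1 --outdir demo
cat > demo/config.yaml <<EOF
counts: demo/counts.tsv
sample_sheet: demo/samples.tsv
annotation: demo/annotation.tsv
k_range: [2, 12]
EOF
ontomodules all --config demo/config.yaml --seed 1 --outdir demo/out
```

The run manifest reports, among other things:

```
"preprocess":  { "n_genes": 3000, "n_timepoints": 30,
                 "replicate_r": { "26": 0.997, ..., "30": 0.998 } }
"fpca":        { "varfrac": [0.565, 0.237], "cumulative_variance": 0.801 }
"clustering":  { "chosen_k": 8,
                 "module_sizes": { "1": 478, "2": 454, ..., "8": 279 } }
"shape_metrics": { "discriminant_accuracy": 1.0 }
```

i.e. the replicated larval/adult samples correlate at r > 0.99, the first
two functional principal components carry ~80% of the trajectory variance,
BIC recovers the eight generating modules, and the four cubic shape metrics
suffice to reclassify every gene into its module. `demo/out/` also contains
the per-gene shape table, module trends, a Newick dendrogram of module
coefficient similarity, all enrichment tables, and the molecular-evolution
outputs. For example `module_ka_summary.tsv` shows the early-embryogenesis
analogue (module 7 here) as the fastest-evolving and ortholog-poorest
module, and the high-expression constitutive module as the slowest:

```
module  n_genes  ortholog_fraction  ka_median  ...
5       370      0.93               0.035
7       303      0.33               0.411
```

while `ka_shape_regression.json` reports that the shape metrics explain a
third of the log-K_A variance in this synthetic scenario
(`r_squared = 0.332`, `F(4, 1935) = 240.9`).

With real data the same config keys point at your count TSV
(featureCounts-style annotation columns are ignored), a sample sheet
(`sample_id  timepoint  minutes  stage  replicate`), a per-gene annotation
TSV (chromosome, domain or position + a breakpoints BED-like file, operon,
gamete class, embryo category, ortholog flag, K_A, K_S), and the full
`k_range: [2, 20]` scan.

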