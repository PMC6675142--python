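# Methods

## Normalisation and filtering

Counts are transformed per sample as
`log2((count + 0.5) / (library_size + 1) × 1e6)`: the 0.5 prior count keeps
zeros finite and the `+1` on the library size keeps the transform bounded.
Replicates are averaged on the log scale, one column per timepoint, and the
mean pairwise Pearson correlation between replicate profiles is recorded
(real developmental series typically show r > 0.95; the synthetic scenario
reproduces r ≈ 0.997 at its default replicate noise).

The expression filter uses *plain* CPM (`count / library_size × 1e6`,
no prior): a gene is kept if its CPM reaches the threshold (default 1,
inclusive) in at least `min_timepoints` timepoints (default 1). By default
CPM is first averaged across replicates within a timepoint; a flag switches
to per-sample evaluation, since either reading of "≥1 CPM in at least one
timepoint" is defensible for duplicated samples. After filtering, log-CPM is
recomputed from the filtered counts so values reflect the reduced library
sizes; if nothing was removed the recomputed matrix is bit-identical.

## Functional PCA

With 30 noise-averaged observations per gene on a regular grid, functional
PCA with uniform quadrature weights reduces exactly to PCA of the
gene × timepoint matrix, so that is the implementation: mean curve =
per-timepoint mean over genes, eigenfunctions = eigenvectors of the T × T
sample covariance of the centred trajectories (divisor n−1), scores = inner
products of centred trajectories with eigenfunctions. No presmoothing is
applied by default; a Gaussian kernel bandwidth (in grid units) is exposed
for sparse or noisy inputs. Postembryonic timepoints are treated as equally
spaced grid positions 26..30 rather than by wall-clock time, because larval
stages have no common minute scale. Each eigenfunction's sign is fixed so
its largest-magnitude entry is positive, making scores platform-stable.
Sparse/irregular per-gene grids and conditional-expectation (PACE) scoring
are out of scope.

## Mixture clustering and model selection

The first two FPC scores feed a full-covariance Gaussian mixture fitted by
EM. The EM loop lives in this package so its contract is explicit:

- initialisation by k-means++ centers (hard-assigned for starting moments),
  10 restarts by default, all seeded through a `SeedSequence` tree;
- convergence when the relative change in total log-likelihood falls below
  1e-8, capped at 500 iterations;
- a ridge floor of `1e-6 × trace(sample covariance)/2` added to every
  component covariance each M-step;
- `BIC = −2 log L + p ln n` with `p = (k−1) + dk + k d(d+1)/2` free
  parameters (weights, means, symmetric covariances; d = 2 here), minimised
  over the scanned k range with ties going to the smaller k.

The test suite cross-checks the fitted optimum against scikit-learn's
`GaussianMixture` under identical settings (agreement to ~1e-12 in
log-likelihood and BIC). Pure EM has a nondecreasing log-likelihood; the
ridge floor shifts the M-step off the exact maximiser, so for a collapsing
component the log-likelihood may dip by an amount on the order of
`n × ridge`. The in-loop monotonicity assertion allows exactly that slack;
strict monotonicity is asserted on well-conditioned data in the tests.

Mixture-component order is arbitrary, so modules are relabelled
deterministically 1..k by decreasing gene count (exact ties broken by
decreasing module mean α). Posterior ties in the hard assignment go to the
lower component index.

## Cubic shape metrics

The basis is built by Gram–Schmidt on {1, t, t², t³} over the timepoint
index rescaled to [−1, 1]: column 0 is all ones and columns 1–3 are
mutually orthogonal, orthogonal to the constant, and scaled to Euclidean
norm √T. Consequently every column has squared norm T, least-squares
coefficients are the independent projections `⟨y, Pⱼ⟩/T`, α equals the
profile mean exactly, βs are invariant to the grid scale, and dropping the
cubic column cannot move α, β₁ or β₂. Module trends are fitted to the
module's mean trajectory (fitting the pooled member points gives identical
coefficients because the design repeats; only the residual sum of squares
differs, and a `pooled` flag reports that variant).

Discriminant validation uses LDA on (α, β₁, β₂, β₃) and reports
resubstitution accuracy by default, since the headline use is a descriptive
"can the four parameters reconstruct module identity" check; a `cv` flag
gives stratified 5-fold accuracy instead, and a singular pooled covariance
falls back to a shrinkage estimator and is flagged. Module coefficient
vectors are related by agglomerative clustering (Euclidean distance,
average linkage by default — the linkage is configurable since no single
choice is canonical), with scipy's deterministic tie-breaking and a Newick
rendering of the tree. Polynomial-degree model selection is deliberately
not performed; the cubic is a fixed descriptive functional form.

## Enrichment

All enrichment tests are 2×2 Pearson χ² on 1 df without continuity
correction by default (a Yates flag exists and the choice is echoed in the
output metadata, since borderline calls depend on it). Degenerate tables
(a zero margin) return χ² = 0, p = 1, flagged. Families and corrections:

- module × chromosome and module × arm/center-per-chromosome: Holm–Bonferroni
  within the family; mitochondrial genes are excluded; the background is the
  analysed (filtered) gene set;
- module × operon / gamete class / embryo category: Bonferroni within the
  family; the universe is restricted to genes annotated for that attribute
  (cross-referenced resources rarely cover the whole transcriptome), so
  unannotated genes are never counted as negatives.

`obs_exp_ratio` is `observed / (module size × category fraction of the
universe)`. Embryo categories may overlap, so that column holds
`|`-separated sets and each category is tested separately. Arm/center
domains can be supplied directly or derived from a BED-like breakpoints
file of 1-based inclusive intervals; a position on a shared boundary
belongs to the interval that starts there. A pooled autosomal arm fraction
per module is reported alongside the per-chromosome tests.

## Molecular evolution

Divergence is summarised by K_A; K_A/K_S is computed on request but not
reported by default because synonymous sites are saturated at the relevant
divergence. Per module: median and quartiles of K_A over members with data,
the fraction below a near-zero threshold (default 0.005 — small enough to
isolate a hyper-conserved histone-like mode while leaving the `< 0.02`
shoulder outside), and the ortholog fraction over all members. Stage
profiles group genes by their peak-expression timepoint (argmax of log-CPM,
ties to the earliest timepoint) under the stage map EE ≤ 120 min,
ME ≤ 390 min, LE ≤ 720 min (embryonic points at 30-minute intervals),
L1–L3 = timepoints 26–28, L4 = 29, YA = 30; stage averages pool genes by the
stage of their peak, and means are geometric (back-transform of mean log
values) with zeros replaced by 0.001 before logging, matching the
convention used for log-scale plots. The TDI weights each gene's K_A by its
linear-scale expression `2^(log-CPM)`; log-scale weights are available
behind a flag but compress the index. The shape regression is OLS of log₁₀
K_A (genes with K_A > 0) on the four shape metrics plus intercept, reported
as R² with the overall F on (4, n−5) df.

## Synthetic data

The generator draws each gene's module from configured weights, builds its
trajectory as `basis × module coefficients + N(0, sd²)` per timepoint
(noise on the log scale, where the pipeline operates), and draws
annotations with module-dependent odds multipliers applied to genome-wide
baselines: chromosome fractions {I 15%, II 17%, III 13%, IV 16%, V 20%,
X 19%}, arm fraction 37%, operon fraction 20.5%, gamete classes
{spermatogenic 15%, oogenic 20%, sex-neutral 55%, unannotated 10%}, and
early-embryo categories {maternal 45%, embryonic 25%, transient 15%,
degradation 15%} on a 34%-annotated subset. K_A is lognormal around a
per-module median (log-sd 0.8) and present only for genes drawn as having
an ortholog. All draws flow from one seed through named `SeedSequence`
substreams, so outputs are byte-reproducible.

The default scenario has 3,000 genes, 30 timepoints, noise sd 0.5 and eight
modules echoing the ontogenetic archetypes: an early-declining module
(α 6, β₁ −3) with high K_A median (0.40), few orthologs (30%), 3× oogenic
and 3× arm odds and 2× chromosome-II odds; two hump-shaped
late-embryogenesis modules with 2× X odds; two adult-peaking modules with
3× spermatogenic odds, 0.1× operon odds and elevated K_A (0.26, 0.19); and
three constitutive modules differing mainly in α, the highly expressed one
operon-rich (3× odds), ortholog-rich (92%) and slowest-evolving
(K_A median 0.033). Separations were chosen so that the full pipeline
recovers the generating partition with ARI ≥ 0.9, as the scenario's
contract requires; in validation all 20 seeds recover k = 8, ARI ≈ 1.0, the
full module K_A median ranking and every 3×-odds enrichment.

What the generator does *not* emulate: realistic read-level noise or
library-size profiles, mean–variance coupling of counts, correlated genes
within modules beyond the shared mean curve, operon positional structure,
or saturated-K_S behaviour. Passing tests therefore demonstrate that the
pipeline's inference machinery is correct and well-calibrated under its own
model assumptions, not that real data satisfy those assumptions. The
optional count export inverts log-CPM at a fixed library size with Poisson
sampling; because the desk-scale gene set does not sum to 10⁶ CPM, the
recomputed log-CPM carries a shared per-timepoint shift, which the FPCA
mean curve absorbs — downstream clustering and shape results are
unaffected.

## Problem sizes and numerical choices

Desk-scale checks use: 1,000 random 2×2 tables (χ² oracle, tolerance
1e-9), 200 random p-vectors (Holm oracle, 1e-12), 200 noiseless cubic
profiles (recovery to 1e-9), a 500 × 30 random matrix (FPCA reconstruction
to 1e-8), 100 random TDI instances, and the 3,000-gene scenario over 20
seeds. The multi-seed BIC scans cover k = 2..10 — bracketing the generating
k = 8 with overfit candidates, where EM routinely runs to the 500-iteration
cap — and the single showcase run scans k = 2..12; a real-data analysis
would scan the configured range (default 2..20). Basis orthogonality is
enforced to 1e-10; covariance floors, tie rules and degenerate-input
behaviour (empty modules, zero margins, zero library sizes, all-filtered
matrices) are as documented above, each with an explicit error or flagged
fallback rather than silent propagation.

## Known limitations

FPCA assumes a shared dense grid (no per-gene missingness). The GMM
operates on two score dimensions; scenarios whose module structure lives in
higher components would need `n_components` raised, and BIC's consistency
then rests on the mixture being a reasonable model of the score cloud.
Resubstitution discriminant accuracy is optimistic by construction (use the
`cv` flag for honest error). Enrichment tests treat genes as independent
draws, ignoring operon linkage and genomic autocorrelation, so p-values on
real data are anti-conservative at fine genomic scales. The TDI inherits
the expression-weighting convention's sensitivity to a few very highly
expressed genes.
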