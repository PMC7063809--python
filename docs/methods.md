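# Methods

This note documents the models and procedures `coexnet` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Network model

Genes are nodes; the edge weight between genes *i* and *j* is the unsigned
soft-threshold adjacency `a_ij = |r_ij|^β`, with `r_ij` the Pearson
correlation across samples. The unsigned convention treats correlated and
anti-correlated genes alike, which matches a factor model in which some
genes may load negatively on a shared latent driver. The power β
sharpens the contrast between strong and weak correlations; its default, 7,
is the reference protocol's value for a 26-sample adipose study, and the
automatic alternative (`power="auto"`) picks the smallest β ∈ {1,…,12}
whose connectivity distribution satisfies the scale-free topology
criterion.

**Scale-free fit.** Connectivities `k_i = Σ_{j≠i} a_ij` are binned into 10
equal-width bins; log₁₀(bin frequency) is regressed on log₁₀(mean bin
connectivity) by unweighted least squares over non-empty bins. The fit's
R² and slope are reported; selection requires R² ≥ 0.8 *and* a negative
slope, with a warned fallback to the maximal-R² candidate. Binning width
and count are not dictated by theory; 10 equal-width bins is the common
convention and is fixed here for determinism.

**Topological overlap.** `TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`
with `ℓ_ij = Σ_{u≠i,j} a_iu a_uj`, `TOM_ii = 1`. Implementation is a
single matrix product (the zero diagonal of `a` makes `(a·a)_ij` equal the
u ≠ i,j sum); the result is symmetrized against floating-point drift,
clipped to [0, 1], and a vanishing denominator (only possible for a fully
saturated pair) maps to the limit TOM = 1. A triple-loop oracle verifies
the matrix form to 1e-10 in the test suite. All matrices are dense double
precision; 5,758² doubles ≈ 265 MB, comfortably in memory, so no blockwise
processing is used. A single-block computation can place module
boundaries slightly differently from a blockwise run of the same
protocol; we prefer exactness of the single block over replicating that
incidental behaviour.

## Module detection

Clustering is average-linkage agglomeration of `d = 1 − TOM` (scipy;
deterministic, ties to the smallest cluster index). The tree cut is a
dynamic hybrid variant built from four deterministic stages:

1. **Adaptive static cut** at `h_min + 0.99·(h_max − h_min)` of the merge
   heights (overridable via `cut_height`), yielding branches.
2. **Branch decomposition.** Within each branch, undersized side-branches
   are peeled off so a handful of stragglers cannot block a genuine
   split, and the branch splits recursively wherever both children meet
   the size floor, up to `deep_split` (default 2) levels. A split or peel
   requires the join to sit strictly above the children's own merges, so
   flat (tied-height) blocks are never subdivided arbitrarily.
3. **Size floor.** Clusters smaller than `min_module_size` (default 10)
   dissolve into the grey class.
4. **Medoid assignment (PAM-like).** Each unassigned gene joins the
   module with the nearest medoid if its distance is within the module's
   radius, defined as the *median* member-to-medoid distance — the median
   (not maximum) keeps a contaminated branch from recruiting everything
   near it.

Modules whose eigengenes are closer than `merge_cut_height = 0.25` in
1 − correlation are then fused (average-linkage on eigengene
dissimilarities, iterated to a fixed point). Because the decomposition in
step 2 may over-split a genuine module, the merge step is what restores
it; the two stages are designed as a pair.

**Membership refinement.** After merging, an optional kME refinement pass
(default on, `membership_alpha = 0.01`) re-assigns every gene to the
module whose eigengene it correlates with most strongly, provided that
correlation clears the module's admission threshold: the larger of the
critical |r| for two-sided significance at α given n, and the module's
median member |kME| minus two Fisher-z standard errors. The second term
makes a coherent module (members near |kME| = 1) reject loosely attached
genes that a diffuse module would accept; the Fisher-z margin prevents
the threshold from ratcheting upward on noisy modules. Genes clearing no
threshold become grey; undersized modules dissolve; the pass iterates at
most 3 times and is deterministic. Refinement substantially improves
recovery of planted modules at n = 26 and makes the noiseless planted
case exact. It can be disabled (`membership_alpha=None`) for a cut that
keeps every branch gene.

Module reassignment by association p-value is disabled: the reference
protocol's reassignment threshold of 0 can never be met, which we read as
disabling that stage.

Colors follow the standard size-ranked sequence (turquoise, blue, brown,
…, magenta 9th, …, darkgreen 22nd); label 0 is grey. Modules beyond the
color list get numbered fallback names.

## Eigengenes and trait association

A module eigengene is the leading right singular vector of the module's
gene-standardized (z-scored per gene) expression, centered and
renormalized to unit Euclidean norm — the raw singular vector is not
exactly mean-zero, and the centered version keeps correlations with
traits identical while satisfying the zero-mean convention. The sign is
fixed so the mean correlation with member genes is positive.
`variance_explained` is the leading singular value's share of total
variance.

Traits are residualized on their declared adjustment covariates by OLS
(categorical covariates 0/1-encoded, reference level alphabetically
first) before correlation; the eigengenes are untouched and the test
keeps n − 2 degrees of freedom. This matches adjusting the *traits* for
sex/race rather than a partial-correlation df correction; with n = 26 and
one or two covariates the practical difference is small. Pairwise-complete
samples handle missing follow-up values; `n_used` is recorded per pair.

Benjamini–Hochberg is applied across all module × trait pairs in one
family by default (`bh_family="matrix"`); per-trait families are
available. The step-up adjustment is implemented directly
(`q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1) and cross-checked against
statsmodels in the tests.

## Hub genes

The connection threshold is the empirical 95 % quantile (linear
interpolation) of the upper-triangle off-diagonal TOM — the unit diagonal
is excluded because it would bias the quantile upward. "Connected" uses
strict inequality; ties at the threshold are measure-zero in continuous
data and the rule must be fixed. Intramodular connectivity counts
same-module connections only; grey genes are excluded. Hubs are the top
⌈0.10 · module size⌉ genes per module by connectivity, ties broken by
gene id and flagged in the output; a pooled-across-modules variant is
available behind a flag.

## Synthetic data

The generator emulates the motivating study design: n = 26 samples,
thousands of genes, block-correlated planted modules, and traits built
from module factors plus sex/race effects plus noise. Gene g in module m
follows `x_g = λ_m f_m + √(1−λ_m²) ε_g` with `f_m`, `ε_g` i.i.d. standard
normal and `λ_m = √(within_module_cor)`, so the population within-module
correlation is exactly `within_module_cor` (the empirical mean |r|
attenuates this by O(1/n); at n = 26 the Monte-Carlo average sits near
0.625 for a population value of 0.64). Background genes are pure noise.
Sex and race are Bernoulli(15/26), mirroring the cohort's composition,
and are re-drawn into two observed levels if a small sample lands
single-level. A configurable fraction of modules (`flipped_fraction`,
default 0) carries negative loadings on half its genes to exercise
unsigned-network behaviour; the default is off so the analytic
`E[r] = λ²` relationship holds without sign mixing. Traits are
`Σ effect·f_m + sex/race shifts + N(0, noise_sd)`; a trait's adjustment
covariates are declared exactly when the corresponding effect is nonzero.

The generator does **not** simulate probe-level noise, batch effects,
platform artifacts, missing expression values, or longitudinal
correlation between repeated trait measurements. Passing tests on this
generator demonstrate correctness of the algorithms under a clean factor
model, not robustness to microarray artifacts.

## Statistical limits at n = 26

Module recovery at the study's sample size is information-limited. With
within-module correlation 0.5 and several hundred background genes, even
an oracle that classifies every gene by its correlation with the *true*
latent factors — the sufficient statistic under the generative model —
attains a full-gene adjusted Rand index of only ≈ 0.88–0.93 per seed:
background genes that chance-correlate with a factor at |r| ≈ 0.5 are
genuinely indistinguishable from module members. The pipeline reaches
mean ARI ≈ 0.77 under those conditions (≈ 0.91 without background genes)
and recovers the noiseless construction exactly. Interpret module
boundaries from 26 samples accordingly: cores are reliable, peripheries
are not.

## Determinism and problem sizes

All analysis stages are deterministic given inputs and configuration;
randomness exists only in the simulator and flows from a single integer
seed (NumPy `default_rng`). Validation simulations use 20 seeds for
module recovery (760 genes), 50 seeds for trait-effect detection
(21 modules × 5 traits = 105 tests per seed) and hub recovery
(20-gene module, 80 background genes); these sizes give stable Monte-Carlo
estimates while keeping the whole validation run in well under an hour on
one core. The screening procedures use scipy's exact F/t distributions;
correlation p-values use the t transform with n − 2 df; BH is exact.

## Known limitations

- Only unsigned networks and the min-denominator TOM; no signed or
  signed-hybrid variants, biweight midcorrelation, or sparsification.
- Single-block computation; very large gene sets (≫ 10⁴) would need
  blockwise processing that is out of scope.
- The tree cut is this package's documented dynamic-hybrid variant, not a
  line-for-line port of any other implementation; on real data module
  counts and boundaries can differ from other WGCNA implementations even
  at identical parameter settings.
- No GO/pathway enrichment; module gene lists export cleanly to external
  enrichment tools.
- Trait adjustment assumes linear covariate effects and a full-rank
  design; no mixed models for the repeated measures.
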