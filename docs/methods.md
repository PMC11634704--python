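# Methods

## The rank-sum engine

For each gene (one column of a cells × genes CSC matrix, stored values
strictly positive) the engine sorts the nonzero values once. The implicit
zeros are the smallest observations, so they occupy ranks 1..n₀ and are
collapsed to the single midrank (n₀+1)/2; sorted nonzeros continue from
rank n₀+1 with tied values averaged. Per-class rank sums are accumulated
in one pass over the stored values: class c's zeros contribute
(n_c − nnz_c)·zero_rank in closed form, so each stored value is visited
exactly once per gene regardless of the number of classes, with O(#classes)
accumulator memory (a flat array indexed by dense class codes assigned in
first-appearance order).

For a one-vs-rest split of sizes n₁ and n₂ = n − n₁ with rank sum R:

- U = R − n₁(n₁+1)/2, so 0 ≤ U ≤ n₁n₂ and U + U_rest = n₁n₂;
- μ = n₁n₂/2, σ² = (n₁n₂/12)·[(n+1) − T/(n(n−1))] with the tie term
  T = Σⱼ(tⱼ³ − tⱼ) over all tie groups, the zero block included;
- two-sided p = erfc(|z|/√2) with z = (U − μ ∓ ½)/σ; the 0.5 continuity
  correction is applied toward the mean and is on by default
  (`continuity=False` disables it).

These conventions — midranks, tie-corrected variance, continuity
correction, normal approximation — are exactly the asymptotic path of the
classical rank-sum implementations, which is what the test suite verifies:
on random sparse matrices the engine's p-values agree elementwise with an
independent dense per-(gene, class) oracle to ≤ 1.5×10⁻⁸ (measured gaps
are at machine precision, ~3×10⁻¹⁶).

Degenerate cases: σ² = 0 (every value in the column tied, e.g. an all-zero
gene) yields z = 0, p = 1 — no evidence against the null. A class equal to
the empty set or to all cells is rejected. Because ranks are invariant
under strictly increasing transforms, raw counts and log-normalized values
produce identical p-values; the test suite asserts this. Exact
(enumeration) p-values and one-sided alternatives are out of scope.

## Marker criteria

`find_all_markers` combines the engine with the conventional
cluster-marker screen. Fold change uses de-logged means: with
log-normalized values x, log_fc = log₂((mean_c[exp(x)−1] + 1) /
(mean_rest[exp(x)−1] + 1)); base-2 logs and pseudocount 1 by default
(natural log available via `fc_base`). pct_1/pct_2 are detection
fractions (fraction of cells with a nonzero value) inside/outside the
class. A gene is a marker for a class iff log_fc > 0.5, adjusted p < 0.05,
and max(pct_1, pct_2) > 0.1 (strict inequalities; all three thresholds are
parameters). Adjustment is Bonferroni over the full gene family per class
by default — the convention of the marker-calling framework this module
replaces — with Benjamini–Hochberg available; the method used is recorded
in the result table's attrs.

Genes that fail the fold-change/detection screen for every class may skip
the rank test (`prefilter=True`, default). They are still reported with
`is_marker=False`; their p is NaN, except genes never detected anywhere,
which are reported with log_fc = 0, p = 1 (their test is degenerate by
construction). Skipping never changes a marker decision, which the suite
checks by running both paths.

## QC and normalization

Cells are kept when min_genes ≤ genes detected ≤ max_genes, total UMI ≤
max_umi and pct_mito ≤ max_pct_mito (defaults 500, 5000, 40 000, 20 %).
The gene floor removes empty droplets, the two ceilings likely doublets,
the mitochondrial ceiling damaged cells; published per-dataset practice
for the mitochondrial cutoff varies over roughly 5–20 %, so the default
sits at the permissive end and pct_mito is taken as a provided annotation
column (a helper computes it from a configurable "MT-" gene-id prefix).
No outlier-adaptive cutoff selection is implemented. Log-normalization
maps v ↦ ln(1 + v·s/T) with cell total T and scale factor s = 10⁴,
preserving the sparsity pattern; zero-total cells are an error naming the
offending cell.

## Age deciles, balancing, trajectories

Donors of each sex are cut into 10 groups at the 10 %…90 % quantiles of
*donor* ages (not fixed 10-year bins, so the groups track the cohort's age
pyramid; left-open/right-closed bins). Every cell inherits its donor's
decile; tied donor ages share a decile, so populations can be unequal.
Fewer than 10 donors, or fewer than 10 distinct donor ages, per sex is an
error. Because the number of detected markers grows with the number of
cells tested, cells are then down-sampled so that every (sex, cell type)
unit keeps the same count in every decile (the minimum across deciles,
uniform without replacement, seeded); units absent from some decile are
dropped with a warning.

On the balanced cells, markers are recomputed within each decile
independently — each cell type versus all other cells of the same sex
decile — and the per-type count is regressed (OLS) on the decile midpoint
age, taken as the mean donor age of the decile; the slope is in markers
per year. The alternative reading (each decile contrasted against the
ensemble) is not implemented. Cell-type composition per (sex, decile) is
computed on the unbalanced cells.

## Drift geometry

`pca_embed` selects the highest-variance genes of the log-normalized
matrix (default 2000, or all available), centers and unit-scales each, and
projects onto the top principal components (default 20; deterministic full
SVD, component signs fixed by making the largest-magnitude loading
positive). Distances use the first 10 dimensions by default: the
convergence analysis dims are explicit in the source analyses, and the
within-subset case, where sources are ambiguous, uses the same default
(both are parameters). Age groups are young < 40, old > 79 years
(configurable endpoints).

Two quantities are computed per (sex, age group): the *within-subset*
distance (mean Euclidean distance of a cell type's cells to their own
centroid) and the *between-subsets* distance (mean distance of all the
group's cells to the group's single global centroid). `detect_regime`
classifies a young/old signature as *dispersion* when every type's
within-subset distance grows with age while the between-subsets distance
moves by less than 10 %, and as *convergence* when the between-subsets
distance shrinks by more than 10 % without a uniform within increase. The
per-type centroid spread (mean distance of type centroids to the global
centroid) is also reported, but the classifier uses the per-cell
between-subsets distance: under a negative-binomial count model, higher
dispersion raises the zero fraction and thereby lowers log-scale means, so
raw centroid spread drifts downward with the dispersion knob even though
type identities are untouched; the per-cell quantity is insensitive to
this mean–variance coupling at the observed magnitudes.

## Aging score

Two formulations are provided, neither privileged: `z_mean` (default) —
per gene, Z-normalize log-normalized expression over all cells, then
average over the (≤ 30-gene) list per cell; `umi_ratio` — the fraction of
a cell's raw UMIs on list genes, in [0, 1] and independent of
normalization parameters (asserted in the suite). List genes missing from
the matrix are dropped with a warning; an empty intersection is an error.

## The synthetic atlas generator

The generator is the package's ground-truth instrument; its defaults are
the study conditions of the test suite.

Counts are gamma-Poisson (negative binomial): gene g in a cell has mean
μ = base_g · lib · (type boost) and variance μ + φμ². Per-gene base means
are lognormal (σ = 1 by default) rescaled by a single bisection-calibrated
factor so the expected zero fraction equals `target_sparsity` (default
0.9, matching typical UMI sparsity; unreachable targets are an error
before sampling). Each cell carries a lognormal library-size factor
(σ = 0.3) so depth normalization is exercised. Each cell type owns a
disjoint block of marker genes whose mean is multiplied by
2^`marker_log2_shift` (default 2) in member cells; marker base means are
floored at the 60th percentile of the base-mean distribution, since a
marker planted on a near-silent gene is undetectable by construction at
any sample size. Donors have uniform ages per sex over `age_range` (or
explicit `donor_ages`, e.g. a young/old two-block design);
`type_proportions` can plant linear compositional drift. Randomness is
split hierarchically with explicit spawn keys (structure / donor / cell),
so adding donors or cells never perturbs existing draws.

Three regimes realize the competing drift mechanisms:

- **dispersion** — an age-linear factor k(age) (default 1 → 3 across the
  age range) scales the within-type heterogeneity. It multiplies both the
  NB overdispersion φ (default base 0.4) *and* the log-sd of a
  mean-corrected lognormal cell-state factor model: each cell draws a
  latent q=3-dimensional state ε ~ N(0, σ_state²I) (σ_state default 0.3)
  that perturbs gene means through fixed loadings. The correlated factors
  are essential: at desk-scale depth (tens to hundreds of UMIs per cell),
  independent per-gene overdispersion is nearly invisible in a
  low-dimensional embedding — uncorrelated noise averages out across genes
  and log1p compresses what remains — whereas coherent state fluctuation
  is exactly what "increased cellular heterogeneity" means geometrically.
  Marker genes carry zero state loading (identity programs modeled as
  tightly regulated), so the state noise widens type clouds without
  moving or blurring centroids.
- **convergence** — the marker shift is scaled by an age-linear factor
  (default 1 → 0.3), moving type centroids toward the global mean with
  age while within-type noise stays at baseline.
- **null** — neither law; baseline heterogeneity only.

The suite verifies the regimes on the generator's own output (count
variance rises with age at constant mean; marker contrast shrinks) before
using them to test the analytics.

## Problem sizes and empirical behavior of the suite

The acceptance-style tests run at desk scale, chosen as the smallest
designs where the studied effects are comfortably identified:

- engine parity: five 300 × 1,000 matrices, density 0.10, 5 classes;
- bookkeeping identities: 10⁴ fuzzed columns over 200 cells;
- marker recovery: 3 types × 200 cells, 2,000 genes, shift 2 (null
  regime) — ≥ 95 % of planted markers, zero false positives, flags equal
  to a brute-force dense pipeline;
- trajectories: 300 genes, 3 types × 40 markers, shift 1.5, base φ 0.6,
  30 single-sex donors × 200 cells, dispersion k 1 → 3 — all-type
  negative slopes in ≥ 19/20 seeds, positive under the reversed law. The
  moderate shift keeps per-decile detection in its power-sensitive range;
  at stronger shifts detection saturates in every decile and the
  dispersion law has nothing to dilute;
- regime separation: 3 donors per age block × 500 cells, 300 genes,
  10 PCA dims on the top 200 variable genes — correct regime called in
  ≥ 19/20 seeds for each regime.

What passing these tests does *not* show: the generator has no batch
effects, doublets, ambient RNA, per-gene outlier structure or realistic
gene–gene correlation beyond the q-factor model, so the results
demonstrate correctness and directional sensitivity of the pipeline, not
effect sizes transferable to real atlases. Real-atlas quantities (decile
r² values, shared DEG catalogs) are expressly not reproduced at these
scales.

## Known limitations

- The normal approximation is inaccurate for very small groups (n ≲ 10);
  no exact test is provided.
- `pca_embed` densifies the selected-gene submatrix; fine at desk scale,
  not for multi-million-cell atlases.
- The balanced-downsampling minimum rule discards data aggressively when
  one decile is thin; consider merging deciles upstream instead.
- The mitochondrial QC threshold is a fixed parameter; no adaptive
  outlier-based selection.
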