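# markerdrift

Sparse one-vs-all Wilcoxon marker detection and cell-identity drift
analytics for single-cell RNA-seq.

## The problem

A standard way to characterize a cell type in scRNA-seq is its set of
*marker genes*: genes significantly higher-expressed in that type than in
all other cells, under fixed fold-change, detection-fraction and adjusted-p
criteria. Tracking how many markers each immune cell type retains across
donor age groups turns "loss of cellular identity with age" into a
measurable quantity — and asks whether an observed decline is driven by
rising within-type transcriptome heterogeneity (*dispersion*) or by
cell-type centroids moving toward each other (*convergence*).

Doing this at atlas scale hinges on a fast one-vs-all-others Wilcoxon
rank-sum test. `markerdrift` implements it the sparse, single-pass way: for
each gene column the nonzero values are sorted once; the implicit zeros,
being the smallest values, share the single midrank (n₀+1)/2; per-class
rank sums are accumulated in one sweep over the stored values, and every
class's U statistic, z score and two-sided p-value fall out of the same
sorted column. For class sizes n₁, n₂ = n − n₁ with rank sum R:

    U  = R − n₁(n₁+1)/2
    μ  = n₁n₂/2
    σ² = n₁n₂/12 · [(n+1) − T/(n(n−1))],   T = Σⱼ (tⱼ³ − tⱼ)
    p  = erfc(|U − μ ∓ ½| / (σ√2))         (two-sided, continuity-corrected)

with the zero block counted as one tie group in T. This reproduces the
asymptotic p-values of the classical reference implementations to well
below 1e-8 while touching each stored value once per gene, independent of
the number of classes.

On top of the engine the package provides: Matrix Market I/O and QC
filtering, log-normalization, a FindAllMarkers-style marker table, per-sex
age-decile construction with balanced downsampling, marker-count-vs-age
trajectories with OLS fits, cell-type composition by decile, PCA
distance-to-centroid dispersion/convergence geometry, signature ("aging")
scores, and a synthetic atlas generator that realizes the dispersion and
convergence regimes with known ground truth.

## Worked example

```python
from markerdrift import (
    SyntheticAtlasSpec, generate_atlas, log_normalize,
    find_all_markers, marker_counts,
)

spec = SyntheticAtlasSpec(
    n_genes=2000, cell_types=("T_naive", "T_effector", "NK"),
    markers_per_type=10, marker_log2_shift=2.0,
    n_donors_per_sex=3, sexes=("F",), cells_per_donor=200,
    regime="null", seed=0,
)
counts, cells, truth = generate_atlas(spec)
print(f"{counts.n_cells} cells x {counts.n_genes} genes, "
      f"sparsity {1 - counts.matrix.nnz / (counts.n_cells * counts.n_genes):.1%}")

lognorm = log_normalize(counts, scale_factor=1e4)
table = find_all_markers(lognorm, cells["cell_type"].to_numpy())
print(marker_counts(table))
```

prints

```
600 cells x 2000 genes, sparsity 89.8%
class
T_effector    10
T_naive       10
NK             9
Name: is_marker, dtype: int64
```

Each cell type was planted with 10 marker genes shifted up by 2 log2 units;
at the default criteria (log₂FC > 0.5, Bonferroni-adjusted p < 0.05,
detected in > 10 % of either group) the pipeline recovers 29 of the 30
planted markers with 0 false positives. The strongest NK markers in the
table look like:

```
  gene   log_fc  pct_1  pct_2        p_adj
G01867 1.931517  0.660 0.2775 6.343594e-22
G01758 2.091727  0.305 0.0725 4.515098e-11
G01733 1.922487  0.330 0.0950 5.713740e-10
```

`log_fc` is the log₂ ratio of de-logged class/rest means (pseudocount 1),
`pct_1`/`pct_2` are the detection fractions inside and outside the class,
and `p_adj` the Bonferroni-adjusted rank-sum p-value.

The same analyses are available from the shell:

```sh
markerdrift simulate --spec spec.json --out atlas/
markerdrift qc --mtx atlas/matrix.mtx --genes atlas/genes.tsv \
    --cells atlas/barcodes.tsv --annot atlas/annot.tsv --out filtered/
markerdrift find-markers ... --out markers.tsv
markerdrift drift ... --seed 7 --out drift_report/
```

`drift` writes `trajectory.tsv` (per-sex, per-type marker counts by age
decile with slope and r²), `composition.tsv`, `dispersion.tsv`,
`convergence.tsv` and, when a gene list is supplied, `aging_scores.tsv`.

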