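# Methods

## Model

`ccpls` treats gene expression regulation by neighboring cells as a
multiple-input multiple-output (MIMO) linear system. For a receiver cell
type *m*, the processed expression of each highly variable gene (HVG) *h*
in cell *i* is modeled as

    y_{i,h} = Σ_f x_{i,f} · w_{f,h} + ε_{i,h}

where *f* ranges over all cell types (including *m* itself — self-type
communication is a valid signal), `x_{i,f}` is the z-scored neighboring
cell-type score, and the coefficient `w_{f,h}` is the direction and degree
of the communication effect reported to the user. Two assumptions are
built in: effects of neighbor types add linearly, and they are shared by
all cells of the receiver type.

## Pipeline

**Step 1 — HVG extraction.** The expression matrix is split by cell-type
label. Within each type, genes that are zero in every cell are dropped;
the rest are normalized (per-cell scaling to the median library size, then
`log1p`) and z-scored per gene. HVGs are selected either by the residual
of a regression of log CV² on log mean across genes (genes above the
`hvg.quantile` residual quantile, default 0.90) or as the `top_n` most
dispersed genes. The exact criterion used by the original single-cell
literature varies; both offered methods are deliberate approximations and
are interchangeable behind the same configuration key. For data that are
already on the processed scale (e.g. the bundled simulator's output),
`normalize: center` performs column centering only — re-z-scoring would
rescale every regression coefficient by the gene's 1/sd and corrupt
coefficient comparisons — and `hvg.method: all` treats every gene as an
HVG.

**Step 2 — neighbor scores.** The raw score of neighbor type *f* at cell
*i* is `Σ_{j≠i, label_j=f} exp(−d(i,j)/dist₀)`, a distance-decay kernel
summed over all other cells; `dist₀` is the minimum positive pairwise
distance of the full coordinate matrix and sets the decay length. The
kernel is exponential by default (a `gaussian` switch exists). Scores are
z-scored per neighbor type within the receiver type's rows; zero-variance
columns are flagged and excluded as predictors. Zero-distance pairs
contribute `exp(0)=1` and are excluded from the `dist₀` minimum
(duplicated coordinates occur in spot-based data).

**Step 3 — PLS regression.** Expression is regressed on the scores by
two-block PLS: outer relations `X = T P′ + E`, `Y = U Q′ + F`, inner
relation `U = T D + H` with diagonal `D`, and the summed coefficient
matrix satisfying the closed form `W = X′U (T′X X′U)⁻¹ T′Y`. Components
are extracted sequentially with deflation of both blocks. The classical
NIPALS inner iteration is a power method whose fixed point is the dominant
eigenvector of the `L×L` matrix `X′YY′X`; we compute that eigenvector
directly by symmetric eigendecomposition. This is numerically identical to
a fully converged NIPALS pass, deterministic, and has no failure mode on
signal-free data, where near-ties among leading eigenvalues make the power
iteration arbitrarily slow. The sign of each weight vector is fixed by
making its largest-magnitude entry positive. The component count *C*
minimizes the mean squared error of 10-fold cross-validation (seeded fold
shuffle; ties go to the smaller *C*; folds are reduced with a warning when
the type has fewer cells than folds).

Per-component coefficients `w_{f,h,c}` are the rank-one increments
`r_c · creg_c′`, where `r_c` is the rotation mapping original `X` to the
score `t_c` and `creg_c` the regression of the deflated `Y` on `t_c`; by
construction they sum to `W` and partial sums reproduce the *c*-component
prediction. The decomposition of the summed coefficient into per-component
pieces is not uniquely determined by the model statement; this choice is
the one under which the filtering step below acts on exactly the terms
that build the prediction.

**Step 4 — two-step filtering.** First, the factor loading of gene *h* on
component *c* — the Pearson correlation between `Y[:,h]` and `t_c` — is
tested with the t statistic `r·√((n−2)/(1−r²))` and Benjamini–Hochberg
adjusted across all (gene, component) pairs. How significance acts on the
coefficients is set by `filter.step1_scope`. The default, `gene`, keeps
the full summed coefficient of every gene significant on at least one
component and zeroes the rest; the alternative, `component`, zeroes the
per-component increments of each non-significant (gene, component) pair
before summation. The gene scope is the default because it leaves
surviving coefficients unbiased: component-wise zeroing clips real
contributions whose loadings sit near the `1/√n` detection boundary, and
with ~100 cells per receiver type that visibly distorts coefficient
blocks (a multiple-input gene cluster can split into two sub-patterns
according to which components happened to pass, and the splits propagate
into the clustering step). The component scope prunes more aggressively
and is retained for sensitivity analysis. Second, the surviving summed
coefficients are tested against a permutation null: each round shuffles
the rows of `X` (breaking every cell's link to its own neighborhood),
refits at the fixed *C*, and records the coefficients; the two-sided
p-value is `(1 + #{|w_perm| ≥ |w_obs|}) / (1 + n_perm)`, BH-adjusted
across all (type, gene) pairs, and entries with `q ≥ alpha2` are set to
exactly zero. Defaults `alpha1 = alpha2 = 0.05`, `n_perm = 999`. The
permutation count bounds the attainable p-value at `1/(n_perm+1)`; with
many true effects competing in the BH ranking, `n_perm` below ~100 can
make even strong effects non-significant, so a warning is emitted for
`n_perm < 99`.

**Step 5 — HVG clustering.** Genes whose filtered coefficients are all
zero are not reported. The rest are clustered by k-means (10 seeded
restarts) on their coefficient vectors, with *k* chosen by the maximal
mean silhouette (Euclidean) over `k ∈ [2, 15]`, clipped to
`n_genes − 1` and to the number of distinct coefficient patterns; ties go
to the smaller *k*; labels are renumbered by descending cluster size.
Fewer than two clusterable genes yield a logged single-cluster result.

**Step 6 — report.** A heat-map table (neighbor types × HVGs ordered by
cluster) and a bipartite edge table `(cluster, neighbor type, mean
filtered coefficient)` with zero-mean edges omitted. A neighbor type is a
*contributor* to a cluster when at least `support_threshold` (default
0.9) of the cluster's genes carry a nonzero coefficient for it and all
such coefficients share one sign.

## Simulator

The generator emulates a single-cell-resolution tissue of ~523 cells with
four equally frequent cell types A–D scattered on a square of unit mean
density with a minimum separation of 0.5 (dart throwing). The separation
rule matters: it makes `dist₀` the same order as the typical cell spacing,
as for physically packed cell bodies, so the kernel integrates over a
biologically sensible neighborhood. Expression is simulated directly on
the processed scale as `y = Σ_f x_f w_f + α·e` (count-scale simulation is
deliberately avoided). The planted coefficient pattern defines four
500-gene clusters: cluster 1 driven by types A and C (the multiple-input
case), cluster 2 by B, cluster 3 by C, cluster 4 unaffected.

Gaussian noise has per-gene standard deviation `σ_h = √(a/μ_h + b)` from
a mean–CV dispersion curve (`a = 1`, `b = 0.1`) with gene means
`μ_h ~ LogNormal(1.0, 0.5)`. The log-normal location was fixed by a
closed-form variance budget: `E[σ²] = a·e^{−1+0.125} + b ≈ 0.52`, which
places the baseline (`w_max = 1`, `α = 1`) variance proportion at
`VP ≈ v̄/(v̄+σ̄²) ≈ 0.7` — the regime in which estimation is expected to
succeed. The gamma variant draws `Gamma(2, 1)` noise per entry,
log-scales and z-scores it per gene (unit per-gene sd by construction).
`VP` is the mean over affected genes of the planted model-term variance
divided by the total expression variance; it is the simulation's
difficulty dial (doubling `w_max` raises it, doubling `α` lowers it).

What the simulator does *not* emulate: spatial tissue architecture
(layers, niches — labels are i.i.d.), count statistics and zero inflation,
correlated noise across genes, cell segmentation error, and cell-type
misannotation. Passing recovery tests therefore demonstrates correctness
of the estimator under the stated generative model, not robustness to
those real-data complications.

## Evaluation

Estimated clusters are matched one-to-one to planted clusters 1–3 by
maximum total overlap (Hungarian assignment on the contingency table);
unmatched estimated clusters and unreported genes map to "others". Ten
indexes summarise a run: ARI over all genes, the Pearson correlation
between estimated and planted coefficients over every (type, gene) pair
(unreported genes contribute zeros), and precision and recall of each of
the four classes. An empty estimated class leaves its precision undefined
(reported as missing, never zero).

## Numerical and design notes

- One run seed is split by `SeedSequence` into per-cell-type substreams
  for CV folds, permutations and k-means, so results are bitwise
  reproducible and independent of which other cell types are processed.
- Cell types with fewer than `min_cells` (default 20) cells are skipped
  with a recorded reason: 10-fold CV needs ≥ 2 cells per fold and the
  variance estimates below that are unstable.
- Degenerate guards: all-zero gene blocks and constant genes are dropped
  with warnings; zero-variance score columns are excluded as predictors
  and reported with zero coefficients; fully coincident coordinates are a
  hard error.
- Test and validation runs use scaled-down problem sizes (tissues of
  200–1000 cells, 40–500 genes per cluster, 99–199 permutations), chosen
  so each property is tested in the regime where it is informative.

## Limitations

- Only 2-D coordinates and single-cell (not spot/multi-cell) resolution.
- No alternative neighborhood definitions (k-NN, Delaunay) and no sparse
  or kernelized PLS variants.
- The two filtering statistics approximate a procedure whose published
  description is partial; they are isolated behind the `filtering` module
  interface so they can be swapped.
- Coefficients are associations under a linear model with an assumed
  kernel; they are not evidence of specific ligand–receptor mechanisms.
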