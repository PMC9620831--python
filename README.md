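# ccpls

Cell–cell communication analysis by partial least squares (PLS) regression
on single-cell-resolution spatial transcriptomes.

Spatial transcriptome methods (seqFISH+, Seq-Scope, MERFISH, …) measure
gene expression in single cells together with their positions. Much of the
cell-to-cell expression variability of highly variable genes (HVGs) within
one cell type is thought to be driven by which other cell types sit nearby.
`ccpls` models that regulation explicitly, for each receiver cell type *m*,
as a multiple-input multiple-output linear system

    y_{i,h} = Σ_f  x_{i,f} · w_{f,h}  +  ε_{i,h}

where `y_{i,h}` is the processed expression of HVG *h* in cell *i*,
`x_{i,f}` is a neighboring cell-type score — the distance-decay sum
`Σ_{j≠i, label_j = f} exp(−d(i,j)/dist₀)`, z-scored within the receiver
type — and `w_{f,h}` is the coefficient reported as the direction and
degree of communication from neighbor type *f* to gene *h*. Coefficients
are estimated by PLS regression (robust in the "small N, large P" regime),
with the component count chosen by 10-fold cross-validation, then passed
through two FDR-controlled filters (a t-test of factor loadings per
component, then a permutation test of the summed coefficients). The
surviving HVGs are clustered by k-means on their coefficient vectors
(cluster count by the silhouette method, k ∈ [2, 15]) and summarised as a
heat map, a bipartite cluster–cell-type graph, and per-cluster contributor
cell types.

The package ships a simulator that plants known coefficients on synthetic
tissue geometry, and an evaluation harness computing ten recovery indexes
(ARI, coefficient Pearson r, precision and recall per planted cluster).

## Worked example

```python
from ccpls import Config, SimulationSpec, simulate_dataset, run_ccpls
from ccpls.evaluate import evaluate_recovery

# 523 cells, 4 cell types, four 500-gene clusters with planted effects
spec = SimulationSpec(n_cells=523, w_max=1.0, alpha=1.0, seed=1)
ds, truth = simulate_dataset(spec)
print(f"simulated {ds.n_cells} cells x {ds.n_genes} genes, VP = {truth.vp:.3f}")

cfg = Config(seed=1, normalize="center", cell_types=["A"])
cfg.hvg.method = "all"        # simulated data are already processed-scale
cfg.filter.n_perm = 199
run = run_ccpls(ds, cfg)
res = run.results["A"]
print(f"components: {res.cv.chosen}, reported HVGs: {len(res.reported_genes)}, "
      f"clusters: {res.clustering.k}")
for q, entries in res.contributors.contributors.items():
    print(f"cluster {q}: " + ", ".join(f"{f} ({d})" for f, d, _ in entries))

report = evaluate_recovery(run, truth, cell_type="A")
for name, value in report.indexes().items():
    print(f"{name:18s} {value:.3f}")
```

prints

```
simulated 523 cells x 2000 genes, VP = 0.705
components: 4, reported HVGs: 1512, clusters: 4
cluster 1: A (up), C (up)
cluster 2: B (up)
cluster 3: C (up)
cluster 4:
ARI                1.000
pearson_r          0.997
precision_1        1.000
precision_2        1.000
precision_3        1.000
precision_others   1.000
recall_1           1.000
recall_2           1.000
recall_3           1.000
recall_others      1.000
```

The variance proportion VP = 0.705 says ~70% of each affected gene's
variance comes from the planted neighbor effects, the rest from noise. The
pipeline reports 1512 of 2000 genes (the 500 unaffected genes are filtered
out, correctly, along with a handful of borderline cases), recovers the
multiple-input cluster driven jointly by types A and C, and scores at or
near 1.0 on all ten recovery indexes. Genes whose filtered coefficients
are all zero are never reported — on label-shuffled pure-noise data the
pipeline reports no HVGs and no communications at all.

The same workflow is available from the shell:

```
ccpls simulate --n-cells 523 --w-max 1.0 --alpha 1.0 --seed 1 --out sim/
ccpls run --expr sim/expression.csv --coords sim/coordinates.csv \
          --labels sim/labels.csv --out run/ --seed 1 --config cfg.yaml
ccpls evaluate --run-dir run/ --truth sim/truth.tsv --out report.json
```

For real datasets, `ccpls run` accepts a dense CSV/TSV or a MatrixMarket
expression matrix with id sidecars plus `cell_id,x,y` and
`cell_id,cell_type` tables, applies median-library/log1p normalization and
mean–CV-residual HVG selection per cell type, and writes per-type
`coefficients.tsv`, `clusters.tsv`, `bipartite_edges.tsv` and a run
summary. See `docs/methods.md` for the model, every tunable parameter, and
the simulator's scope.

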