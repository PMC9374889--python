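# conndyn

Network-control-theory dynamics of structural brain connectomes: per-region
**average controllability**, **modal controllability** and
**synchronizability**, supercontroller identification, covariate-adjusted
group statistics, linear-SVM group classification, and clinical-scale
prediction with an improved connectome-based predictive modeling (CPM)
scheme. A synthetic-cohort generator makes the entire pipeline testable
offline, end to end.

The package is aimed at network-neuroscience analyses of case–control
cohorts (e.g. schizophrenia and bipolar disorder versus healthy controls)
whose subjects are described by weighted, symmetric streamline-count
adjacency matrices over an atlas parcellation, plus age/sex covariates and
clinical symptom scales.

## The model and metrics

Each subject's connectome is a nonnegative symmetric matrix *A* (zero
diagonal) whose entry *a*<sub>ij</sub> counts white-matter streamlines
between regions *i* and *j*. Linear discrete-time dynamics are placed on the
**stabilized** matrix Ā = *A* / (1 + σ₀(*A*)), σ₀ the largest singular
value, so the spectral radius is below one:

```
x(t+1) = Ā x(t) + B_K u_K(t),        B_K = e_k  (one control node at a time)
```

- **Average controllability** of node *k* is the trace of the
  infinite-horizon controllability Gramian
  W<sub>k</sub> = Σ<sub>τ≥0</sub> Ā<sup>τ</sup> e<sub>k</sub>e<sub>k</sub>ᵀ Ā<sup>τ</sup>,
  which for symmetric stable Ā equals the *k*-th diagonal entry of
  (I − Ā²)⁻¹ — computed in closed form. High values mark nodes that can
  drive the network to easy-to-reach states with little input energy.
- **Modal controllability** is φ<sub>i</sub> = Σ<sub>j</sub> (1 − λ<sub>j</sub>²) v<sub>ij</sub>²
  over the eigenmodes Ā = VΛVᵀ; high values mark nodes able to steer the
  system into fast-decaying, difficult-to-reach modes.
- **Synchronizability** is the inverse normalized spread of the nonzero
  graph-Laplacian eigenvalues,
  1/σ² = d̄²(N−1) / Σ<sub>i</sub>(λ<sub>i</sub> − λ̄)², with
  d̄ the mean coupling strength per node; a regional split distributes the
  spread over nodes through the Laplacian eigenvector loadings.

Downstream, the pipeline identifies **supercontrollers** (regions whose
group-mean metric exceeds the across-region mean + 1 SD), runs omnibus
ANOVA and age/sex-adjusted two-tailed contrasts with nodal-level Bonferroni
correction, computes rank-based partial correlations between metrics and
clinical scales, classifies groups with a linear SVM under stratified
k-fold CV with strictly in-fold feature selection, and predicts scale
scores with leave-one-subject-out CPM (within-fold Spearman selection of
positively/negatively correlated features, z-scored sums, multiple linear
regression).

## Worked example

Simulate a two-group cohort (105 HC vs 45 SZ, 60 regions) in which region 5
(0-based) of the SZ group carries a 1.2-SD increase in average
controllability, then test, threshold and classify:

```python
import conndyn as cd

spec = cd.CohortSpec(
    n_regions=60,
    group_sizes=(("HC", 105), ("SZ", 45)),
    effects=(cd.Effect(group="SZ", metric="average", regions=(5,), size_sd=1.2),),
    seed=1,
)
cohort = cd.generate_cohort(spec)

gc = cd.adjusted_group_test(cohort, "average", "SZ-HC", level="regional", bonferroni_m=60)
print(gc.table[gc.table.p_corrected < 0.05])

hc_mean = cohort.metrics["average"][cohort.group_mask("HC")].mean(axis=0)
sc = cd.supercontroller_regions(hc_mean, cohort.region_ids, metric="average", group="HC")
print(sorted(sc.regions, key=int), sc.threshold)

res = cd.classify_cohort(cohort, "SZ-HC", k=10, seed=0)
print(res.pooled_accuracy, res.auc)
```

Output:

```
target  statistic            p  p_corrected direction
     6   7.950149 4.660296e-13 2.796177e-11     SZ>HC

['48', '50', '56', '57', '58'] 5.008
0.873 0.896
```

The injected region (atlas label "6" = 0-based index 5) is the only one
surviving Bonferroni correction, with the expected SZ > HC direction; five
high-strength hub regions exceed the HC supercontroller threshold; and the
structural group difference supports well-above-chance classification
(pooled 10-fold accuracy 87%, AUC 0.90).

The same stages are available from the shell:

```sh
conndyn simulate-cohort --out cohort/            # manifest + matrix files
conndyn metrics --manifest cohort/manifest.csv --out metrics.csv
conndyn group-stats --manifest cohort/manifest.csv --out stats.csv
conndyn classify --manifest cohort/manifest.csv --contrast SZ-HC --out cls.csv
conndyn run-all --config run.yaml                # everything, with a run report
```

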