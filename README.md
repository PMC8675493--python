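# therascore

Drug-response heterogeneity in single-cell RNA-seq.

Tumours are rarely homogeneous: subclones of the same sample can respond
differently to the same drug, and bulk transcriptomics averages those
differences away. `therascore` scores **every cell** of a preprocessed
scRNA-seq experiment against collections of bidirectional drug signatures
(UP/DN gene-set pairs from perturbation experiments or pharmacogenomic
sensitivity screens), summarises each signature's response homogeneity in a
single statistic, groups cells into **therapeutic clusters** — sets of cells
sharing a common response to a set of drugs — and ranks the drugs that
differentially target a chosen cell group. It is aimed at computational
biologists exploring treatment options and resistance structure in tumour
scRNA-seq data, and works equally on functional gene-set collections.

## The score and the switch point

For a signature with gene sets *UP* and *DN*, each direction is scored per
cell as the mean expression over the signature genes present in the matrix,
then normalised across cells (multiplied by the cell's detection fraction to
penalise dropout, winsorised at the 1st/99th percentiles, median-centred).
The signed net score

&nbsp;&nbsp;&nbsp;&nbsp;net<sub>i</sub> = up<sub>i</sub> − dn<sub>i</sub>

is min–max rescaled to [0, 1] per signature. The **switch point (SP)** is
the image of net = 0 on that scale — the value where cells switch from a
down-regulated to an up-regulated status:

* **SP = 0** — every cell responds in the up direction (for a sensitivity
  signature: a uniformly sensitive population);
* **SP = 1** — uniformly resistant;
* **intermediate SP** — a heterogeneous population, with
  scaled > SP exactly for the net-positive cells.

Downstream, scores are covariate-regressed (KNN imputation + QR residuals),
clustered (PCA → Leiden on a kNN graph, UMAP for display) and prioritised:
per-group summary statistics, a 4-squares classification on the residuals'
mean (x) vs switch point (y) plane, a permutation-based differential drug
ranking with BH-FDR, and drug–drug correlation modules. Signature
construction from bulk pharmacogenomic tables (OLS t-statistics of a
treated contrast or of the AUC slope, with tissue confounder adjustment,
top-N/bottom-N cuts, drug-specificity-score background selection) is
included. See `docs/methods.md` for the full model description.

## Worked example

The package ships a synthetic-data module that plants known structure, so
the whole workflow runs without downloads. The default configuration is
500 cells in two equal clones scored against a 6-drug panel; the responsive
clone is shifted 3σ on drugs `sig0`–`sig2`, with 30% dropout and a
library-size nuisance covariate:

```python
import therascore as ts
from sklearn.metrics import adjusted_rand_score

expr, drugs, clone, covars = ts.simulate(ts.SimConfig(seed=7))
scores = ts.bc_score(expr, drugs)
print(scores.switch_points.round(3).to_string())

scores = ts.regress_out(scores, covars, ["nUMI"])
red = ts.reduce_scores(scores, use="residuals", n_pcs=5, seed=7, embed=False)
tcs = ts.find_clusters(red, seed=7)
print("ARI vs planted clones:",
      round(adjusted_rand_score(clone, tcs.labels), 3))
print(ts.rank_differential(scores, clone, n_perm=1000, seed=7).round(4))
```

prints

```
sig0    0.416
sig1    0.425
sig2    0.419
sig3    0.555
sig4    0.533
sig5    0.585
ARI vs planted clones: 1.0
           effect  p_value     fdr      scale
signature
sig0       0.4481   0.0010  0.0020  residuals
sig1       0.4362   0.0010  0.0020  residuals
sig2       0.4213   0.0010  0.0020  residuals
sig3      -0.0145   0.2088  0.3132  residuals
sig5      -0.0087   0.4675  0.5610  residuals
sig4       0.0053   0.7483  0.7483  residuals
```

Read: all six switch points are intermediate — each drug sees a mixed
population (half the cells respond), exactly what was planted. Clustering
the residualised score matrix recovers the two clones perfectly (ARI 1.0),
and the differential ranking puts the three truly responsive drugs on top at
the smallest attainable permutation p-value (1/1001, BH-adjusted), while the
three null drugs show near-zero effects.

The same pipeline runs from the shell on TSV/GMT inputs:

```sh
therascore simulate --out data/ --seed 7
therascore run --config run.yaml        # score → regress → cluster → rank
```

where `run.yaml` names the expression matrix, the GMT file, the metadata
table, the covariates to regress and the seed; every artefact (score
matrices, switch points, cluster labels, embedding, rank tables, plots and
a JSON manifest with input checksums) lands in the configured output
directory, and re-running the same configuration reproduces it byte for
byte.

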