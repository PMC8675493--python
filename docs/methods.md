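# Methods

## The model

therascore quantifies heterogeneity of predicted drug response in a
single-cell RNA-seq experiment. The input is a preprocessed (normalised,
log-scale) cells × genes expression matrix and a collection of drug or
functional signatures, each a pair of gene sets: the genes most up-regulated
(`UP`) and most down-regulated (`DN`) in the phenotype the signature
describes. Two signature families are supported and share the same scoring:

* **perturbation signatures** — transcriptional changes induced by drug
  treatment (a control-vs-treated contrast). A high score means the cell's
  transcriptome resembles the treated state.
* **sensitivity signatures** — pre-treatment transcriptional correlates of
  drug response, built with the area under the dose–response curve (AUC) as
  a continuous covariate. By the sign convention used throughout (`UP` =
  higher in resistant, high-AUC samples), a high scaled score marks a cell
  whose transcriptome looks resistant.

### Per-cell score

For one signature and one direction (UP or DN), the raw score of cell *i* is
the mean expression over the signature genes present in the matrix
(the sum divided by the number of present genes, so missing genes shrink the
denominator rather than contributing zeros). Raw scores are then normalised
in three separately toggleable steps, applied across cells:

1. **dropout penalty** — multiply by the detection fraction
   f_i = (# signature genes with expression > 0 in cell i) / (# present
   genes). A cell detecting none of the genes is pulled to 0 regardless of
   its raw value.
2. **winsorisation** — clip at the across-cell 1st/99th percentiles
   (configurable), damping outlier cells.
3. **median centring** — subtract the across-cell median, so 0 marks typical
   activity and the sign of the score is meaningful.

The exact normalisation used by the original R implementation of this idea
is not published in detail; the three steps above implement its stated
intent (penalise cells with many zeroes and/or outliers) while being fully
specified and testable. The steps can be toggled off individually
(`penalise_zeros`, `winsor=(0, 100)`, `centre`) to approximate variants.

### Switch point

The net score is `up − dn` for bidirectional signatures, `up` or `−dn`
alone for unidirectional ones. Per signature, the net scores are min–max
rescaled to [0, 1]; the **switch point (SP)** is the image of net = 0 on
that scale, clamped to [0, 1]:

* SP = 0 — every cell has a non-negative net score (a uniformly
  "up-regulated" / sensitive population);
* SP = 1 — every cell non-positive (uniformly resistant);
* intermediate — a heterogeneous population, and
  `scaled > SP ⇔ net > 0` cell by cell.

**Boundary convention.** When the population is homogeneous the un-clamped
image of zero falls outside [0, 1] and is clamped, so the extreme cell sits
exactly on the SP; the strict equivalence above therefore holds for interior
SPs, and at a clamped endpoint it holds with `≥` on the closed side. A
constant net score carries no direction information: all cells are assigned
0.5 and SP = 0.5, with a warning. A signature with zero gene coverage yields
a NaN column; a cell that merely detects zero signature genes still gets a
(maximally penalised) finite score, keeping the matrix dense for clustering.

### Regression of unwanted variation

Scores inherit technical covariation with library size, gene detection and
cell cycle. `regress_out` removes it in two steps: NaN entries are imputed
by a k-nearest-neighbour average (k = 10; distance = Euclidean over mutually
finite signature columns, donors = the k nearest cells with a finite value
in the target signature; ties broken by cell order), then per-signature OLS
residuals of the scaled scores on an intercept + numeric covariates +
one-hot dummies (first level dropped) are computed via QR projection.
Residuals stay signed (mean 0 per signature) and are **not** re-rescaled;
the switch point remains the one computed at scoring time, so downstream
prioritisation combines a scoring-scale SP with residual-scale means. The
imputer is hand-rolled because the common library implementation weights
distances by the number of missing coordinates, which is not the contract
documented here.

### Therapeutic clusters

Cells are clustered on the (residualised) score matrix, not on expression:
the resulting groups are response phenotypes and can cut across
transcriptional clusters. The pipeline is PCA (default 20 components,
clipped below min(n_cells, n_signatures)) followed by Leiden community
detection on a 15-nearest-neighbour graph at resolution 0.4 (k-means is
available as a deterministic fallback), plus a 2-D UMAP embedding for
visualisation. All stochastic steps take the single run seed; labels are
renumbered by decreasing cluster size. A zero-variance score matrix embeds
all cells at the origin with a warning (there is no structure to embed).

### Prioritisation

`bc_stats` reports, per (signature, cell group): switch point, mean, median,
sd, variance (n−1 denominator), min, max, proportion of NaN and the
residuals' mean. The 4-squares classification for a chosen group uses the
residuals' mean (x) vs the switch point (y): `bottom_right_most_sensitive`
needs SP ≤ 0.1 and a residuals' mean at or above the group's 0.9 quantile;
`top_left_least_sensitive` mirrors it (SP ≥ 0.9, ≤ 0.1 quantile);
intermediate SPs with extreme residual means are differentially
(in)sensitive; everything else is unclassified. The SP cuts (0.1/0.9) and
the residual-mean decile are configuration defaults — the quadrant idea
fixes the axes but no published cutoffs exist — and deciles mirror the
decile logic used for the drug background.

`rank_differential` ranks signatures by the difference of condition means of
the residuals (scaled scores, with a warning, when regression has not run),
with two-sided permutation p-values (default 1000 label permutations,
add-one correction) and Benjamini–Hochberg FDR across signatures. A
permutation test was preferred over a parametric one because scaled scores
are bounded and distinctly non-Gaussian. `correlation_modules` groups
signatures by average-linkage hierarchical clustering of 1 − |Pearson r|
across cells, cut at 1 − 0.7.

## Signature construction

`de_statistic` fits, per gene, OLS of expression on either a treated
indicator (perturbation contrast) or the AUC (sensitivity design), plus
one-hot tissue-confounder dummies, and returns the t-statistic of the drug
term. Plain OLS t-values are used deliberately: moderated-variance
(empirical-Bayes) machinery is out of scope here, and the operative output —
the gene ranking — is the same object. Genes expressed identically in every
sample get t = 0. Confounder levels with a single sample are dropped with a
warning in the continuous design; a rank-deficient design is an error.

`make_signature` cuts the top/bottom N genes (default N = 250, following
the established practice for this signature size; the examples in this
repository use smaller N matched to their planted-set sizes). Ties at the
top cut are broken towards the lexicographically smaller gene id, at the
bottom cut towards the larger, which keeps the two tails disjoint even when
all statistics tie.

**Drug specificity score (DSS).** Each signature is scored per cell-type
group (group mean of mean-UP − mean-DN expression); the DSS is
`1 − mpd / max_mpd`, where mpd is the signature's mean pairwise absolute
difference of per-type scores and the maximum runs over the collection.
A signature inducing the same pattern in every cell type scores 1, the most
type-specific signature 0. The published description of this score defers
its formula to a reference; this rescaled mean-pairwise-difference form
preserves the stated behaviour (similar cross-type patterns ⇒ high DSS) and
is monotone in pattern similarity, but is not guaranteed to match the
original numerically. The background selection takes the first and last
deciles by DSS (⌈0.1·n⌉ signatures each, ties broken by name).

## Synthetic data

The single-cell generator works directly at the normalised log-expression
level (count-level simulation is a documented extension point; scoring never
sees counts): per-gene baseline means ~ N(2, 0.7), unit-variance cell noise
(so effects are in σ units), planted clones shifting signature UP genes up
and DN genes down, Bernoulli dropout zeroing entries, and a log-normal
per-cell library-size factor multiplying all genes and recorded as the
`nUMI` covariate. An optional off-target block lets clones differ in
expression without differing in response, so that score-based clusters can
be shown to track response rather than expression.

The default configuration is the package's reference study condition:
500 cells, 2000 genes, two equal clones, a 6-drug panel (25 UP + 25 DN genes
per signature) in which the responsive clone is shifted 3σ on a 3-drug
family, dropout 0.3, libsize_sd 0.2. A 6-drug panel is the smallest in
which clustering the score matrix is a meaningful multi-signature problem —
with only two signatures the score matrix has a single usable principal
component and community detection on it degenerates. What the generator
does **not** emulate: count noise and depth-dependent dropout, doublets,
batch structure, correlated gene modules outside the planted blocks, and
partial-responder clones; recovery results on it are therefore best-case
and say nothing about signature quality on real data.

The bulk pharmacogenomic generator plants, per drug, resistance genes whose
expression gains `effect · (AUC − 0.5)`, draws AUC as Uniform(0, 1) plus a
tissue shift (±0.2 per tissue level, making tissue a genuine confounder of
response), and optionally adds tissue-only offsets to a disjoint gene block
to exercise confounder adjustment.

## Numerical choices and degenerate inputs

* Gene matching is exact, case-sensitive string equality; an `uppercase`
  read flag exists for users mixing symbol conventions (default off).
* Winsor limits default to (1, 99) percentiles; symmetric limits preserve
  the exact UP/DN antisymmetry (swapping the gene sets maps net → −net,
  SP → 1 − SP, scaled → 1 − scaled).
* Empirical p-values use the add-one correction, so the smallest attainable
  p is 1/(n_perm + 1) and constant signatures get p = 1 exactly.
* KNN imputation requires every cell to have at least one finite score;
  all-NaN signatures are dropped with a warning.
* TSV round-trips are exact: floats are written with round-trippable `repr`
  and parsed back with `float()`, not a lossy fast parser.
* All randomness (PCA solver, UMAP, Leiden, k-means, permutations,
  simulation) flows from explicit integer seeds; re-running a pipeline
  configuration reproduces every artefact byte for byte.

## Problem sizes used in the shipped checks

The test-suite and the acceptance script run entirely on synthetic data
generated at run time: the 500-cell reference condition above for recovery
and regression checks; 50-cell random instances for the brute-force oracle
comparisons; 200 replicates of a 30-cell null for permutation calibration;
50 samples × 1000 genes for the signature-builder checks; and a
100-signature collection for the background-decile arithmetic. These sizes
keep the full suite under a minute of compute (UMAP JIT compilation aside)
while leaving every statistical check adequately powered.

## Known limitations

* The normalisation and DSS are contract-faithful reconstructions, not
  numerical ports of the original R implementation; scores should not be
  compared across the two implementations.
* Plain OLS t-statistics are noisier than moderated t at small sample
  sizes; for fewer than ~15 samples per drug the gene ranking is unstable.
* The differential ranking tests mean shifts only; variance-only or
  multimodal response differences will not rank.
* No gene-identifier conversion (symbol ↔ Ensembl) and no HDF5/loom
  readers; inputs are TSV/MatrixMarket/GMT.
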