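# Methods

## The model

`edgestage` classifies the stage of a tumour sample — `normal`, `I`, `II`,
`III`, `IV` — from bulk (or pseudobulk) gene expression, using features
attached both to genes (*nodes*) and to gene pairs (*edges*). The premise
is that disease perturbs not only expression levels but the joint behaviour
of interacting gene pairs, and that a single sample's perturbation of a
normal-cohort reference is informative about its stage.

### Normal-reference pair model

For each pair (x, y) in the pair universe (by default physical
protein–protein interaction edges restricted to the retained genes), the
reference stores sufficient statistics over the n normal samples: means
x̄, ȳ, centred sums of squares SS_x, SS_y and the cross-product sum
S_xy. These determine

- the reference correlation `PCC_n = S_xy / sqrt(SS_x · SS_y)`,
- the reference covariance `COV_n = S_xy / (n − 1)`,
- the least-squares line `y = b0 + b1·x`, `b1 = S_xy / SS_x`,
  `b0 = ȳ − b1·x̄`.

Pairs with zero variance in either gene over the normals are dropped at fit
time (count logged). The pair is oriented with the lexicographically
smaller identifier as x; the regression predicts y from x. This
orientation is a documented convention — the data do not fix a direction.

### Single-sample edge features

A query sample with pair values (x*, y*) yields three features per pair:

- **ΔPCC** = PCC over the n reference samples plus the query, minus
  `PCC_n`. Computed by a rank-one update of the stored sums
  (`SS' = SS + (n/(n+1))·d²` with d the deviation from the reference
  mean), identical to recomputing from the concatenated n+1 points to
  ~1e−12 (tested against a brute-force oracle). Bounded in [−2, 2].
- **ΔCOV** = the covariance of the augmented set minus `COV_n`. The
  reference uses the sample convention (denominator n−1) and the augmented
  (n+1)-point set uses its own sample convention (denominator n); the
  choice of estimator is ours and is applied consistently.
- **residual** = `y* − (b0 + b1·x*)`, the signed vertical distance from
  the reference line.

When the query is itself one of the reference normals (featurising the
training cohort), the reference is first refit leave-one-out without that
sample via a rank-one downdate, so a sample never perturbs a model that
already contains it. Degenerate augmented sets yield feature 0 with a
warning rather than an error.

### Node features

Per-stage differential expression against the normal group uses a
pluggable two-sample test on log2 expression — Wilcoxon rank-sum by
default, Welch's t optionally — with Benjamini–Hochberg adjustment per
stage and a call threshold of q ≤ 0.05 and |log2 FC| ≥ 1 (both
configurable; genes constant in both groups get p = 1). Node candidates
are the genes called in **every** stage (intersection, not union): the
stage-consistent changes. Externally computed DEG lists (e.g. from a
count-model tool such as edgeR) can be supplied instead of the built-in
test; the built-in test operates on log-scale values and makes no
count-distribution assumptions.

### Ranking and integration

Candidate features of each type are ranked by random-forest
impurity-decrease importance averaged over the training fits of a seeded
stratified 10-fold split (a single full-data fit is available by
configuration). Forest defaults: 100 trees, unlimited depth, √p features
per split, seed 42. 100 trees (rather than several hundred) keeps the
composition search below ~0.1 s per fit on one CPU; ranking stability
across seeds is part of the test suite (Spearman ≥ 0.7). A recursive
feature elimination with cross-validation (`rfecv_select`) prunes the
lowest-importance 10% per iteration while recording the F1-versus-size
curve.

The integrated panel is found by enumerating *compositions*
(c_node, c_ΔPCC, c_residual, c_ΔCOV), each count ≥ 1, taken as strict
rank-order prefixes of the per-type rankings, bounded by
`max_per_type = 6` per type and `max_total = 20` overall (≤ 1296
cross-validated evaluations; prefix search keeps the enumeration
polynomial). Each composition is scored by stratified 10-fold
cross-validated multi-class F1; ties are broken by smaller total, then
lexicographic composition, so results are fully deterministic. **Macro**
averaging is the default because stage classes can be an order of
magnitude apart in size (weighted averaging is a switch). The deployed
classifier is refit on all samples with the winning composition; reported
F1 always comes from the search's cross-validation, never from the refit.

A note on runtime: the full default grid at 10 folds is ~10⁴ forest fits
and takes tens of minutes on one CPU. The test suite and the acceptance
script therefore run the search either at reduced bounds or at a fixed
total budget of 11 features (104 compositions), which is also the
fixed-budget comparison the package reports (`compare_feature_types`).

## The synthetic cohort generator

No public staged cohort ships with the package; the generator produces
cohorts with exactly the structure the method assumes, so every stage of
the pipeline is testable end to end with known ground truth.

Expression is generated directly on the log2 scale: gene baselines ~
U[3, 10] (typical log2 RNA-seq range), Gaussian noise with sd 1.0, values
floored at 0 (≈0.1% of entries; negligible for every moment used). The
pair universe is a **forest**: each pair introduces one new "child" gene
conditioned on an existing "parent" via
`z_child = ρ·z_parent + sqrt(1−ρ²)·ε`, with per-pair baseline ρ ~
U[0.4, 0.9]. This makes every pair's population correlation exact by
construction while allowing more genes (300) than pairs (200). The default
design uses 60 samples per class so 10-fold stratified CV is well posed; an
`imbalanced` preset reproduces a 59/266/120/84/26-shaped class profile
scaled down.

Planted signal, all sets disjoint:

- **node**: 10 reserved genes outside the universe get per-stage mean
  shifts 2.0/2.5/3.0/3.5 log2 (stages I–IV) — graded so node features are
  stage-discriminative, strong enough that a 60-vs-60 rank-sum test at
  q ≤ 0.05, |lfc| ≥ 1 calls them essentially always.
- **ΔPCC**: 8 pairs drawn with within-stage correlation ρ + Δρ·s,
  default Δρ = −1.2 (infeasible combinations are rejected at validation).
- **ΔCOV**: 8 pairs whose child deviations are multiplied, scaling the
  covariance by up to `cov_scale = 6` at full severity while leaving the
  correlation unchanged.
- **residual**: 8 pairs whose child is displaced off the reference line by
  1.2 log2 units at full severity.

Edge effects are multiplied by per-stage severity 0.4/0.6/0.8/1.0 so
perturbation grows with stage (progressive rewiring), which also makes
edge features carry stage information rather than a binary tumour/normal
contrast.

The three edge perturbations are not orthogonal, and cannot be: changing a
pair's correlation at fixed variances *is* a covariance change, and an
amplitude change moves the augmented correlation through the influence
function. The defaults were chosen from this calculus: a Δρ pair shifts
ΔCOV by ≈ Δρ·σ²·s/n, a γ-scaled pair shifts ΔPCC by ≈ −ρ(γ−1)²/(2n) —
a quantity that *saturates* relative to its own spread as γ grows — while
a variance-only signal's mean/sd separation is capped at ρ/√(1+ρ²). Hence
the covariance factor is large (6) and the correlation change strong
(−1.2): each type then dominates its own feature's ranking, and residual
cross-leakage (e.g. a Δρ pair appearing in the covariance top-20, as real
pairs do across published top-feature tables) is absorbed by the 20
ranking slots against 8 planted pairs per type.

What the generator does **not** emulate: RNA-seq count noise (negative
binomial), library-size or batch effects, correlated measurement error,
non-Gaussian marginals, and realistic network topology (hubs, dense
modules). Passing tests therefore demonstrate that the statistical
machinery does what it claims under its own assumptions — not that the
defaults are tuned for any particular real cohort.

## Numerical choices and degenerate inputs

- Zero-variance pairs are excluded at reference fit; augmented-set
  degeneracy (possible only at numerical noise level, since augmentation
  cannot reduce a positive sum of squares) yields feature 0 plus a
  warning.
- The leave-one-out downdate clips sums of squares at 0 to absorb
  floating-point cancellation; it requires ≥ 4 normal samples.
- BH q-values come from `statsmodels`; importance ties in rankings break
  lexicographically by feature name so rankings are byte-reproducible.
- Stratified folds are auto-reduced (with a warning) when the smallest
  class has fewer members than the fold count; a class with < 2 members is
  an error.
- The low-expression filter removes genes whose zero fraction is
  *strictly greater* than the threshold (default 0.5), is idempotent, and
  preserves gene order.
- The log transform is fixed to log2(x+1), matching the convention of the
  public expression matrices this tool targets; the config records it.

## Open design points, resolved

- **Classification task**: 5-class including `normal` by default
  (`include_normal` switches to 4-class), since normal samples are part of
  every cohort profile the tool targets.
- **Pair universe scope**: fully configurable — supplied interaction edges
  (default) or all pairs among the intersection DEGs, capped at a
  deterministic lexicographic cut (`max_fallback_pairs = 2000`).
- **Importance estimation**: fold-averaged by default; a full-data fit is
  one configuration switch away.
- **Fold assignment**: stratified and seeded; unstratified 10-fold with a
  26-member class can produce folds with zero members of that class.

## Known limitations

- Impurity-decrease importance is biased toward high-cardinality/
  high-variance features; permutation importance is not implemented.
- The composition search optimises the CV point estimate and does not
  propagate fold variance into the argmax; near-ties are resolved by the
  minimal-total rule, not by significance.
- Edge features assume an approximately linear pair relationship in the
  normal cohort; strongly nonlinear pairs are summarised only through the
  residual feature.
- The incremental statistics are exact, but a reference of n < ~10
  normals makes all three features noisy; the tool warns about nothing
  here beyond the n ≥ 3 (fit) and n ≥ 4 (leave-one-out) floors.
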