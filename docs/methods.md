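# Methods

## Structured Y coding

A coding scheme is an ordered list of factor blocks. A categorical block
with k levels occupies k columns of Y; a sample's row holds the block's
`on` value in its level's column and the `off` value elsewhere. An ordinal
block occupies one column holding the level's coded value; codes must be
strictly monotone in level order. Off/on values and ordinal codes are
scheme data, not constants, because PLS fits Y in the least-squares sense:
a block whose columns carry more variance pulls the solution harder, so the
coded scales are the instrument for balancing blocks (e.g. a 0/6 one-of-k
block next to dosage codes 0–6 and time codes 0/1/6, giving all blocks a
comparable worst-case error).

Crisping inverts the coding for raw predictions: arg-max within each
categorical block, nearest coded value for each ordinal block. Ties are
deterministic: arg-max ties resolve to the lowest level index, and an exact
ordinal midpoint resolves to the lower coded level. Both rules are
arbitrary conventions; they matter only on measure-zero inputs but make
runs reproducible. Crisping is invariant to any strictly increasing affine
transform applied uniformly within one categorical block's columns.

The per-sample error is the number of misassigned blocks (Hamming distance
between label tuples), i.e. the error set {0..B} for B blocks: wrong in one
factor is strictly better than wrong in two.

### Variance balance diagnostic

`variance_balance` encodes a design and reports, per block, the sum and the
per-column mean of the Y column variances. The warning ratio is the
max/min of the per-column *means* (threshold 4 by default, an
order-of-magnitude guard). The mean is used rather than the sum because a
k-column one-of-k block inherently carries about k times the total variance
of a single ordinal column even when the two are scaled comparably per
column; a sum-based ratio would flag exactly the mixed categorical/ordinal
schemes the method is designed for. Block totals are still reported so a
user can judge aggregate dominance directly.

## PLS2 engine

NIPALS with deflation of both X and Y; mean centring only (no unit-variance
scaling — matching the intended use on peak-area tables where relative
scale carries information). Inner-loop convergence is declared when the
weight vector changes by less than 1e-10 (max 500 iterations per
component). Each component's sign is flipped so the largest-magnitude
weight entry is positive, which makes repeated fits bit-identical. If the
residual covariance degenerates (constant Y, rank exhausted), fitting stops
early with fewer components and a logged notice rather than an error.

NIPALS components are nested — the first A components of a larger fit equal
an A-component fit — so one fit per left-out sample serves every candidate
component count during leave-one-out selection. Coefficients at truncation
A are `B_A = W_A (P_A' W_A)^-1 Q_A'`; prediction is
`(X_new - x_mean) B_A + y_mean`.

## Double cross-validation

The unit of splitting is the biological replicate: each outer iteration
holds out one randomly chosen replicate from every populated design cell as
the blind test set (for a 5x4 design with 3 replicates: 20 test, 40
training samples). Cells with a single replicate are rejected — the
held-out sample would have no same-cell training support. On the training
set a leave-one-out pass scores every candidate LV count 1..max_lv by mean
crisped block error; the smallest count achieving the minimum is chosen
(the mean and the total misassignment count give the same argmin). The
default cap is min(15, n_train - 2, p): structured Y matrices genuinely
need many latent variables, but the cap keeps LOOCV fits well-posed.

Per iteration and per factor, the test predictions are tallied into a k x k
confusion matrix of true vs predicted level; row-percentages are averaged
over iterations (a row absent in an iteration contributes nothing that
iteration). Overall CCRs and conditional CCRs (factor A's accuracy within
each true level of factor B) are computed from the pooled tallies, so the
conditional CCRs weighted by stratum sizes reproduce the overall CCR
exactly; empty strata are reported as missing. The default iteration count
is 1000; the tests and the acceptance script use 100 (and 50 for the larger
incomplete design) to keep runtimes in minutes — sampling noise on a CCR at
100 iterations is well under the tolerances used.

### Permutation test

Each iteration also runs the identical pipeline once with permuted labels:
the whole design row (the label tuple together with its replicate id) is
reassigned to a random sample before splitting. Reassigning intact rows —
rather than permuting factor columns alone — keeps the cell/replicate
structure valid for the replicate-stratified splitter while still breaking
any association between labels and features. The per-block p-value is the
fraction of iterations where the observed test error strictly exceeded the
null error. Ties count as non-exceedances, making the estimate slightly
anti-conservative (a p of exactly 0 is possible and common for strong
effects); this literal counting rule is kept because it is the convention
the confusion-matrix machinery is paired with.

Whether labels should be permuted before or after the outer split is a
genuinely open choice; permuting before the split (within each iteration)
was chosen so that the null run exercises exactly the same pipeline,
including the split.

## VIP scores

Per Y column k: `VIP_jk = sqrt(p * sum_a SS_ak (w_ja/||w_a||)^2 / sum_a
SS_ak)` with `SS_ak = q_ak^2 t_a't_a` — the standard definition, under
which the mean squared VIP over variables is exactly 1 for every column. A
column the model explains no variance for is rejected with a diagnostic
rather than returning 0/0. Block summaries take, per variable, the maximum
VIP over the block's columns; a single-column ordinal block's summary is
the column itself. When no LV count is supplied, the VIP model is fitted on
all samples with the count most frequently selected across double-CV
iterations (smallest on ties) — a configurable convention, since the
"right" fitting set for a post-hoc importance plot is not uniquely defined.

## Synthetic data generator

Features are additive Gaussian: baseline 0, plus per-factor effects on a
random subset of features, plus i.i.d. N(0, noise_sd²) noise. A
categorical factor contributes an independent N(0, effect_size²) offset per
(level, affected feature); an ordinal factor contributes slope x
standardised code, slope ~ N(0, effect_size²) per affected feature, so
`effect_size` is in noise-sd units per 1-sd change of the coded level in
both cases. An optional pairwise interaction adds cell-specific shifts the
same way. Everything (masks, shifts, noise) derives from one seed.

Presets:

- `riboswitch_like` — complete 5x4 design, 3 replicates (60 samples), 200
  features; strong 5-level factor (2.5 sd, 20% of features), weak 4-level
  factor (0.8 sd, 20%), noise sd 1. A third design column `batch` aliases
  the replicate index and carries no effect: a built-in negative control
  whose CCR should sit at chance (1/3) and whose permutation p should be
  insignificant. Aliasing it to the replicate keeps the 5x4 cell structure
  usable for replicate-stratified splitting.
- `propranolol_like` — incomplete 3x4x3 design (the pre-exposure time point
  exists only at control dosage), 4 replicates (108 samples); categorical
  strain effect 2.0 sd, linear-in-code dosage (codes 0/2/4/6) 1.2 sd and
  time (codes 0/1/6) 1.0 sd, 20% affected features each. Effect sizes were
  chosen once as a realistic "clear but not trivial" regime for a
  peak-table study of this size.

What the generator does *not* emulate: heavy-tailed/log-normal intensity
distributions, correlated features, retention-time drift, batch trends or
missingness mechanisms of real GC-MS tables. Passing recovery tests
therefore demonstrate that the pipeline's machinery is correct under its
own linear-additive assumptions, not that real studies will reach the same
rates; the structured-vs-binary contrast on synthetic data is checked
directionally, never against published magnitudes.

KNN imputation fills a missing cell with the mean of the feature's values
over the k nearest samples, using Euclidean distance on mutually observed
features rescaled by the fraction observed (k = 5 default in the pipeline;
a feature with no observed values is rejected by name). The computation is
delegated to scikit-learn's `KNNImputer`, which implements exactly this
dialect.

## Numerical and degenerate-input choices

- LV candidates are additionally capped at n_train - 2 so every inner
  leave-one-out fit satisfies A <= n - 1.
- Confusion rows are averaged only over iterations in which the row was
  populated; with complete designs every row is populated every iteration.
- All randomness flows through `numpy` SeedSequences spawned from one user
  seed; reports are byte-identical across reruns with the same inputs.
- Reported CSV percentages are rounded to 2 decimal places; the JSON
  summary keeps full precision.

## Known limitations

- One model variant only (NIPALS PLS2, mean centring); no O-PLS, sparse or
  kernel variants, no autoscaling.
- Interactions are not coded into Y; they are inferred post hoc from
  conditional CCRs.
- The permutation p-value's strict-inequality convention is
  anti-conservative near p = 0 and the minimum resolvable p is
  1/n_iterations.
- The double CV is expensive (outer iterations x training samples PLS fits);
  iteration counts in the low hundreds are practical on one core, and the
  confusion-matrix estimates stabilise well before 1000 iterations.
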