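# Methods

This note records the model behind `clusterbalance`, the conventions that
are deliberate choices rather than consequences, and what the synthetic
tests do and do not establish.

## Data model and preprocessing

A `LabeledTable` holds an n×d float matrix, 0/1 labels (0 = majority
"no", 1 = minority "yes") and a schema tagging each column `binary` or
`continuous`. The distinction drives everything distance-based:
`standardize` z-scores continuous columns (population denominator n,
zero-variance columns map to 0) and passes indicator columns through
unchanged, so Euclidean distances weight a 1-sd hormone difference the same
as a flipped indicator. Location/scale are fitted on the training split
only and applied to any other table.

`clean` is deliberately minimal and deterministic: all-null columns are
dropped (the reference file carries one), rows lacking a target are dropped
at load time, remaining missing cells are imputed by column median
(continuous) or mode (binary, ties to 0), and winsorization of continuous
columns is available but off by default. These rules are this package's
own choices; the upstream description of cleaning is too terse to
reconstruct, and determinism was the deciding criterion.

`split` uses floor(ratio·n) training rows from a seeded permutation.
Stratification is off by default — the reference class counts after an
80:20 split (5340/192 train, 1326/58 test from 6666/250) are consistent
with an unstratified shuffle, not a proportional one.

## Resamplers

All neighbour queries are exact, with ties broken by (distance, row index)
ascending, so every resampler is a deterministic function of (data, seed).

**SMOTE.** Synthetic minority rows are `x + λ(n − x)`, λ ~ U[0,1), with `n`
drawn among the `k_neighbors1 = 5` nearest minority neighbours of a
uniformly drawn minority row `x`. Pairs are drawn until the equalizing
target (minority count = majority count) is met, rather than synthesizing a
fixed count per point: the per-point-per-neighbour literal reading cannot
hit an exact parity target, and the post-balancing counts are the
observable contract. When the minority has m ≤ 5 rows, the neighbour count
drops to m − 1; below 2 rows interpolation is impossible and an error is
raised.

**ENN / KNN editing.** One pass; a row is deleted when a *strict* majority
of its k nearest neighbours (3 for ENN, 5 for the KNN variant) carries the
other label. A tied vote keeps the row. Deletions are computed against the
original table and applied simultaneously, making the result independent of
row order; the rule applies to both classes (both classes are observed to
shrink in the reference counts). Editing is anti-extensive but not
idempotent — no second pass is taken.

**NearMiss.** Fixed to NearMiss-1: each majority row is scored by its mean
distance to its 3 nearest minority rows and the minority-count
smallest-score rows are kept. The version is this package's choice; the
method family is named upstream without a variant.

## Cluster-wise balancing

`cluster_balance` runs the elbow scan and k-means on training features only
(labels excluded from the geometry — clustering on the label would leak the
target into the resampling neighbourhoods), SMOTEs each cluster to local
parity, and edits per cluster by default. A `scope="global"` switch edits
once after merging instead; the per-cluster default follows the procedure's
prose description, the global variant its pseudocode, and both are kept
because the two disagree. Clusters with fewer than two minority rows, or
with a single class, pass through untouched.

The per-cluster SMOTE target is the *local* majority count, not the global
one. Merged counts therefore approximately — not exactly — equalize, which
matches the reference behaviour (e.g. 5340/5025 after the proposed
balancing). A post-condition asserts the merged ratio lies within
[1/1.25, 1.25] and sets a report flag (with a warning) otherwise; heavier
label noise can legitimately exceed the band because editing removes
noise-seeded rows asymmetrically.

**Elbow rule.** SSD(k) is the best-of-5-restarts k-means inertia for
k = 1..10 (k_max is configurable; 10 comfortably contains the reference
choice of 5). "Sharpest decrease" is operationalized as the maximizer of
the discrete second difference of **log** SSD. The log scale matters: with
unequally spaced clusters the raw-SSD curvature is dominated by the first
merges (k = 2) regardless of the true k, while relative drops peak at the
planted cluster count. A chord-distance ("knee") rule is available behind
`method="knee"`. When the largest curvature is less than twice the
runner-up the scan sets a flat-curve flag — single-mode data exercises this
path — and the argmax is still reported.

K-means itself is standard machinery, delegated to scikit-learn's seeded
k-means++ behind the `kmeans()` surface; the reported SSD is recomputable
from centroids and assignments and is asserted so in tests.

## Evaluation protocol

`run_experiment` splits 80:20, standardizes on train, balances the training
side only, runs stratified 5-fold CV on the balanced training table for
stability statistics, then fits on the full balanced table and reports on
the untouched test split. CV never produces the headline numbers — the
single held-out split does; the two roles are kept separate because mixing
them is the easiest way to overstate a resampler.

Reported precision/recall/F1 are support-weighted per-class averages by
default (under which accuracy ≡ weighted recall, asserted numerically, and
precision can exceed accuracy on skewed tests); the binary (positive-class)
mode is retained for diagnostics. The 0/0 convention for precision/recall
is 0. AUC is the trapezoid over the grouped-threshold ROC sweep, which
equals the tie-corrected normalized Mann–Whitney statistic; the test suite
asserts that identity against an independent rank-sum oracle.

The nine classifier configurations ship as frozen hyperparameter maps
(e.g. AdaBoost 50 × 0.01, RF 100 trees, SVM rbf C = 1, XGB 100 × 0.1, all
`random_state = 42`) bound to scikit-learn/xgboost estimators through a
fit/predict/score adapter. Re-tuning them is out of scope.

## Expert alignment

Interview tabulation: frequency = row sum over doctor columns; rank 1 when
every doctor selected the feature, rank 2 when at least half (rounded up)
did, rank 3 otherwise. These thresholds were inferred from the complete set
of printed (frequency, rank) pairs, which they fit exactly; they are
documented as inferred, not stated. Survey scores are 3·high + 2·medium +
1·low. Levels cut a ranking into High/Medium/Low by fixed counts (default
(2, 7, 11), copying the reference partition of 20 features) or by the two
largest score gaps (`method="gap"`), since the level-cut rule for the
model-side ranking is not stated upstream. The two expert instruments are
reported separately; no fusion rule is invented. Concordance reports
per-feature level matches, the match fraction (symmetric), Spearman ρ of
serials, and the disagreement list.

Shapley-style attributions are consumed, never computed: any
(feature, score) vector can be fed in; the shipped native scorer is
permutation importance (mean metric drop over seeded column shuffles, ties
broken by feature order).

## Synthetic generator

The generator emulates exactly the features the method's assumptions touch:

* exact class counts pre-noise (defaults 6666/250);
* five spherical Gaussian sub-populations on the 6 continuous columns, with
  one-hot centres `separation = 8` apart (≈ 2.4 within-cluster sd after
  z-scoring, given the between-cluster variance the layout induces) —
  separated enough that cluster recovery is near-exact, so elbow tests
  probe the rule rather than the data;
* minority mean shifts on the hormone-like columns — TSH 1.5 sd > T3 1.0 >
  TT4 0.7 > T4U 0.5 > FTI 0.3, Age unshifted. The magnitudes are moderate
  on purpose: hormone panels overlap the reference range, and a minority
  this overlapped is genuinely hard for a classifier trained on raw
  imbalanced data — the regime cluster-wise balancing exists for. A large
  `class_shift` override produces the cleanly separable regime when a test
  needs a ceiling;
* indicator columns Bernoulli with patterned base rates in [0.05, 0.30] and
  a +0.12 minority offset;
* an all-NaN junk column (on by default) mirroring the reference file, so
  the cleaning path is exercised end to end;
* uniform label flips at `label_noise_frac` (default 0), giving the editors
  something to remove.

`planted_truth` returns cluster assignments, pre-noise labels, flipped
indices and the planted effect-size order for recovery tests.

What passing these tests shows: the pipeline's contracts (no leakage,
within-cluster interpolation, determinism, count arithmetic, directional
benefit under noise) hold on data satisfying the method's assumptions.
What they do not show: performance on real thyroid data, whose clusters are
not spherical, whose indicators are correlated, and whose label noise is
not uniform. The generator is a stand-in for testing, not a claim about
thyroid physiology.

## Problem sizes and numerical choices

Tests run the full-size table (6916 rows) where a contract is about the
reference counts or planted recovery, and a few-hundred-row version of the
same generator elsewhere; oracle-equivalence suites use ≤ 200-row instances
where exhaustive scans are exact and cheap. k-means tolerance is 1e-4 with
max 300 Lloyd iterations; neighbour queries chunk the distance matrix (512
query rows per block) to bound memory; all λ draws, permutations and
restarts derive from explicit integer seeds, and per-cluster SMOTE seeds
are offset by cluster index so clusters draw independent streams.

## Known limitations

Binary targets only; dense matrices only; single-pass editing; NearMiss-1
only; the elbow rule, like any curvature heuristic, is undefined on truly
flat curves (flagged, not resolved); the balance-ratio band is a diagnostic
contract, not a guarantee under arbitrary noise.
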