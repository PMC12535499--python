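# Methods

This note documents the modelling choices in mzlipid: what is computed,
under which assumptions, with which defaults, and where the edges are.

## Problem statement

Given an untargeted LC–MS feature table (m/z, retention time, ionization
polarity, optional HMDB identification), learn a binary classifier
*lipid* vs *non-lipid* from two predictors — the mobile-phase composition
at elution and m/z — using the identified subset as labelled data, and
select among candidate model families by multi-metric rank aggregation.

## Gradient model

A single linear ramp from `a_start` %A to `a_end` %A over `ramp_minutes`,
optionally shifted by a dead-volume delay `t_delay`:

    %A(t) = a_start + slope · (t − t_delay),   slope = (a_end − a_start) / ramp_minutes

Before the ramp the composition holds at the start value; after it, at the
end value (isocratic hold), so the conversion is total on t ≥ 0 and
%A + %B = 100 everywhere. The slope is stored as the exact endpoint ratio;
rounding (e.g. 60/13 → 4.615) happens only in reports. The ramp inversion
`time_at_composition` is defined only inside the program's composition
range.

**Assumption:** the gradient is a single linear segment. Multi-step
programs are out of scope; model one segment or pre-convert externally.

## Curation rules

1. **RT window** — keep `rt_low < RT < rt_high` (defaults 1 and 14 min);
   both boundaries exclusive. Early features sit in the dead-time region,
   late ones in wash/re-equilibration.
2. **Polarity deduplication** — an HMDB accession observed in both
   ionization modes is kept only in the preferred mode (default negative).
   Unidentified features are never touched by this rule.
3. **Labelling** — identified features are *lipid* iff their HMDB super
   class equals "Lipids and lipid-like molecules" (case-insensitive,
   configurable). Unidentified features and accessions missing from the
   taxonomy extract are excluded, never defaulted to a class.

The curation report partitions the input exactly (labeled + RT-excluded +
polarity-dropped + unidentified + unmapped = input), which is asserted at
run time.

## Predictors

The fixed predictor order is `(gradient_pct_a, mz)`. Gradient composition
is the dominant predictor (HILIC retention tracks polarity); keeping it
first means that when the correlation-based reduction step finds the two
predictors redundant, the rule "drop the later column" removes m/z.

## Preprocessing conditions

Twelve canonical conditions: every combination of `reduce`, `balance`, and
one of `normalize` / `scale` (the two standardizers are mutually
exclusive), plus the untouched `basic`. Step order is fixed:
reduce → balance → normalize|scale.

- **reduce** — drop the later column of any predictor pair with
  |Pearson r| ≥ `reduce_threshold` (default 0.9), computed on the training
  partition.
- **balance** — oversample the minority class to parity by
  nearest-neighbor interpolation: each synthetic point is
  `x + u·(neighbor − x)` with `u ~ U[0,1)`, `neighbor` one of the
  `k_neighbors` (default 5) nearest minority neighbors in Euclidean
  predictor space. Originals are preserved; synthetics are appended. This
  is implemented in-package rather than via an external oversampling
  library because the operation is part of the framework surface and the
  dependency is not guaranteed in the runtime environment.
- **normalize** — center to mean 0 and scale to unit SD (ddof = 1);
  **scale** — divide by SD without centering. A zero-variance predictor
  passes through unchanged with a warning.

All state (kept columns, centering/scaling statistics, synthetic points)
is fitted strictly on the training side of the active split; evaluation
partitions are only transformed. Balancing is never applied to evaluation
data.

## Model families and tuning

Ten families, each with a finite ordered default grid (fully overridable):

| family | backend | tuned |
|---|---|---|
| naive_bayes | GaussianNB | var_smoothing |
| decision_tree | CART, gini | ccp_alpha, max_depth, min_samples_leaf |
| trimmed_decision_tree | CART, depth ≤ 4 | ccp_alpha, min_samples_leaf |
| svm | RBF SVC + sigmoid calibration | C |
| random_forest | probability forest (500 regression trees) | mtry, min leaf |
| boosted_tree | gradient boosting | trees, learning rate, depth |
| lasso / ridge / elastic_net | penalized logistic | penalty strength (+ l1_ratio) |
| knn | k-nearest neighbors | n_neighbors |

Notes:

- The **trimmed decision tree** is a deliberately restrained tree —
  depth capped at 4 and cost-complexity pruned — tuning only pruning
  strength and leaf size. It trades lipid recall for less overfitting.
- The **penalized logistic** family standardizes predictors internally
  before fitting (glmnet-style), so the penalty acts on comparable scales
  under every preprocessing condition.
- **SVM probabilities** come from Platt-style sigmoid calibration fitted
  by internal 5-fold CV on the (fold-internal) training data the model
  receives.
- The **tree ensembles run on xgboost**. The random forest is a
  *probability forest*: 500 regression trees fitted to the 0/1 outcome
  with row subsampling (0.632), per-split candidate-predictor sampling,
  and exact minimum-leaf counts (unit hessians under squared error make
  `min_child_weight` an exact leaf-size bound). Averaged leaf means are
  class probabilities. This matches the behaviour of R-style probability
  forests and is roughly an order of magnitude faster than the
  scikit-learn ensembles at 500 trees, which is what keeps the full
  120-combination grid inside a minutes-scale budget on one CPU.

Tuning walks the documented grid order, scores each point by mean 10-fold
CV accuracy (a failed fit scores 0 with a warning), takes the first
maximum on ties, and refits the winner on the full condition-transformed
training partition. All seeding is derived deterministically from the run
seed via a CRC-based label hash, so runs are exactly reproducible.

## Splitting

Stratified 75/25 train/test split with per-class half-up rounding of test
counts (226 + 68 examples at 25% give a 57 + 17 test set). CV folds are
stratified by dealing each class round-robin into folds after a seeded
shuffle, keeping per-fold class counts within one example of proportional.

## Metrics and model comparison

- **Accuracy** at the 0.5 probability threshold.
- **ROC AUC** via the tie-corrected rank statistic (Mann–Whitney form),
  identical to trapezoidal integration over all thresholds.
- **PR AUC** per class (non-lipid positive and lipid positive), using the
  non-increasing precision envelope over recall (interpolated precision),
  integrated step-wise across tied-score blocks. Under class imbalance the
  lipid-positive PR AUC is the most demanding of the four metrics.

Families are compared by ranking each metric across models (higher is
better; ties get the average of the tied positions), summing the four
ranks, and ranking the rank sums the same way. Each metric's ranks sum to
n(n+1)/2. Selection ties at the top-k boundary break by accuracy rank,
then declaration order.

## Synthetic generator

Class-conditional draws, fully reproducible from a seed:

| parameter | default |
|---|---|
| n_features | 5000 |
| identified fraction | 0.06 |
| lipid prevalence among identified | 0.23 |
| lipid %A at elution | truncated normal, 23 ± 2 |
| non-lipid %A at elution | truncated normal, 45 ± 12 |
| lipid / non-lipid m/z | 550 / 280, SD 120, truncated to [70, 800] |
| dual-polarity rate | 0.20 |
| RT-artifact rate | 0.05 |

Retention times are derived by inverting the gradient ramp from the drawn
compositions, so annotating the generated table with the same program
recovers the planted class structure exactly — the loop is closed for
end-to-end testing. Artifacts overwrite RT into the excluded regions
((0, 1] and [14, 20) min); dual-polarity duplicates carry ppm-level m/z
jitter and small RT jitter.

The `separation` knob multiplies the gap between the class %A means
**anchored at the lipid mean**: lipid-like compounds elute at the ramp
start regardless of the rest of the chemistry, so only the non-lipid mean
moves. Anchoring at the midpoint instead would push the lipid mean below
the program's composition floor at high separation, which the generator
must reject. Presets: `default` (1.0), `separable` (2.0), `overlapping`
(0.3), `balanced` (prevalence 0.5).

Problem sizes in the examples and tests (3,000–8,000 features) are chosen
so that the identified subset lands in the few-hundred-example range
typical of curated metabolomics studies while keeping runs fast.

## Numerical choices

- Floats are parsed locale-independently (decimal point only); malformed
  rows are rejected with their row index rather than silently coerced.
- Sample SDs use ddof = 1 throughout.
- Child seeds derive from `crc32` over (seed, labels…), masked to 31 bits.
- The ROC rank statistic and the PR envelope estimator are exact (no
  resampling); both are property-tested against brute-force oracles.

## Limitations

- Two predictors only; isomeric classes that overlap in both m/z and
  elution composition are not separable by construction.
- Single linear gradient segment; no multi-step program support.
- The labelled training subset is assumed representative of the
  unidentified majority — a selection-bias assumption the framework cannot
  check internally.
- HMDB taxonomy input is a pre-extracted two-column table; XML parsing is
  out of scope.
- The synthetic generator is a structural emulation for testing and
  demonstration, not a physical chromatography model; absolute metric
  values on synthetic data do not transfer to real acquisitions.
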