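# mzlipid

Classify untargeted LC–MS metabolomics features as **lipid** vs **non-lipid**
from just two numbers per feature: the mass-to-charge ratio (m/z) and the
retention time (RT).

## The scientific problem

Untargeted LC–MS experiments detect thousands of features — (m/z, RT) signal
pairs — of which typically only a few percent can be matched to a known
metabolite. Everything else is chemically anonymous. Yet even an anonymous
feature carries class information: under hydrophilic interaction
chromatography (HILIC), lipid-like compounds are poorly retained and elute
early, while polar metabolites spread across the gradient. A classifier that
separates "lipid" from "non-lipid" using only m/z and RT can therefore
annotate the unidentified majority of a feature list at the super-class
level, guiding downstream identification effort.

Raw RT is a poor predictor across laboratories because it depends on the
instrument, column and method. mzlipid instead converts RT into the
**mobile-phase composition at elution** (%A, the aqueous share) through the
gradient program — a linear ramp such as 20 → 80 %A over 13 min has slope
60/13 ≈ 4.615 %A/min, so %A(t) = 20 + 4.615·t on the ramp. Composition at
elution transfers between setups running the same gradient shape; RT does
not.

## What the package does

1. **Gradient conversion** (`mzlipid.gradient`) — a linear-ramp gradient
   model with optional dead-volume delay; converts RT → (%A, %B) and inverts
   the ramp.
2. **Curation** (`mzlipid.curation`) — excludes features eluting at or
   outside the usable 1–14 min window, resolves metabolites identified in
   both ionization polarities in favour of one mode (negative by default),
   and labels identified features *lipid* iff their HMDB super class is
   "Lipids and lipid-like molecules". The curation report partitions the
   input exactly: every feature is accounted for once.
3. **Model selection** (`mzlipid.learning`, `mzlipid.models`,
   `mzlipid.evaluation`) — crosses 12 preprocessing conditions (combinations
   of correlation-based reduction, minority oversampling, centering/scaling)
   with 10 model families (naive Bayes, decision tree, trimmed decision
   tree, SVM, random forest, boosted tree, lasso/ridge/elastic-net logistic
   regression, k-nearest neighbors) for 120 combinations. Each is grid-tuned
   by stratified 10-fold cross-validation on a stratified 75/25 training
   split, with all preprocessing state fitted fold-internally (no leakage).
   Each family's best combination is scored on the held-out test set with
   four metrics — accuracy, ROC AUC, and PR AUC with each class as positive
   — and the families are compared by tie-aware rank aggregation: rank each
   metric across models (ties get average ranks), sum the four ranks, rank
   the sums. The top-k models can then be applied, without refitting, to an
   external validation table.
4. **Synthetic data** (`mzlipid.synthetic`) — a class-conditional generator
   of realistic feature tables (unidentified majority, RT artifacts,
   dual-polarity duplicates, truncated-normal class structure in %A and
   m/z), used by the examples and the test suite.
5. **CLI** (`mzlipid` console script) — `init`, `simulate`, `run`, `rank`,
   `predict`, with a JSON run manifest, config hashing and a persisted model
   bundle.

## Worked example

`examples/03_model_selection.py` runs the complete workflow on a reduced
grid (3 preprocessing conditions × 4 families) over a 3,000-feature
synthetic table. Its actual output:

```
best condition and CV accuracy per family:
  decision_tree  basic      CV 0.959 tuned {'ccp_alpha': 0.0001, 'max_depth': 2, 'min_samples_leaf': 10}
  knn            normalize  CV 0.959 tuned {'n_neighbors': 3}
  naive_bayes    basic      CV 0.983 tuned {'var_smoothing': 0.0}
  lasso          basic      CV 0.975 tuned {'penalty_strength': 0.0001}

held-out test rank table:
               accuracy  roc_auc  pr_auc_nonlipid  pr_auc_lipid  rank_sum  final_rank
model
lasso             0.951    0.994            0.998         0.983       4.0         1.0
naive_bayes       0.927    0.987            0.965         0.967       9.5         2.0
knn               0.927    0.969            0.986         0.843      10.5         3.0
decision_tree     0.902    0.884            0.931         0.789      16.0         4.0

selected top models: lasso, naive_bayes
lasso test confusion: tp=9 fp=1 tn=30 fn=1
```

The other examples cover gradient conversion
(`01_gradient_conversion.py`), simulation + curation
(`02_simulate_and_curate.py`), and rank aggregation over an externally
printed metrics table (`04_rank_aggregation.py`). The same workflow is
available from the shell:

```bash
mzlipid simulate --n-features 5000 --seed 1 --out-dir synthetic
mzlipid init --out run.yaml        # edit paths: discovery/taxonomy
mzlipid run run.yaml               # artifacts + manifest.json in output_dir
mzlipid predict mzlipid_out/models.pkl new_features.tsv --out predictions.tsv
```

On the default synthetic scenario the selected models recover the planted
structure: the decision tree's root split lands on gradient composition
near 26–27 %A (just above the lipid elution band at ~23 %A), and the random
forest attributes ≈ 96% of its split importance to gradient composition
versus m/z.

## Reproduction

`scripts/acceptance.py` recomputes the package's headline quantities — the
gradient slope, the 120-combination grid cardinality, the tie-aware rank
aggregation of a fixed set of published per-model metrics (including all
fractional tied ranks and rank sums), the overall accuracies implied by
per-class confusion counts, and a full 5,000-feature end-to-end run — and
writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run takes a few minutes on one CPU (the 120-combination grid dominates).

## Layout

```
src/mzlipid/     library (gradient, io, curation, learning, models,
                 evaluation, synthetic, pipeline, config, cli)
examples/        narrative scripts, one per capability
tests/           pytest suite incl. tests/test_acceptance.py
scripts/         acceptance.py (headline-quantity reproduction)
docs/methods.md  methods note: model, assumptions, parameters, limitations
```
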