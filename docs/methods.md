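# Methods

## The model

`gradvote` implements a weighted soft-voting ensemble for binary
classification on tabular clinical-style data. Five base learners —
logistic regression (LR), a decision tree (DTC), a random forest (RFC),
k-nearest neighbours (KNN) and a multi-layer perceptron (MLP) — are each
tuned by exhaustive grid search under stratified k-fold cross-validation
and refitted on the training part. For a subset S of the tuned models, the
ensemble's positive-class probability for instance j is

    ŷ_j = clip( Σ_{i∈S} w_i · p_ij , 0, 1 )

where `p_ij` is model i's predicted P(class 1) and `w` is a real-valued
weight vector. The weights are fitted by plain gradient descent:

* **Initialization.** Either uniform (`w_i = 1/n`) or random — n draws
  from U[0,1) normalized to sum to 1. Immediately after initialization the
  weights lie on the simplex; descent steps are unconstrained, so fitted
  weights can individually exceed 1 and need not sum to 1.
* **Monitored loss.** The ε-stabilized binary cross-entropy
  `−(1/N) Σ [y log(p+ε) + (1−y) log(1−p+ε)]` with ε = 1e−10, evaluated on
  both the training and validation parts each iteration.
* **Update direction.** By default the gradient used for the update is
  `∇L_i = (1/N) Σ_j (ŷ_j − y_j) p_ij` — the exact gradient of the
  squared-error surrogate `(1/2N) Σ (ŷ_j − y_j)²`, not of the monitored
  BCE. This pairing (BCE for monitoring/early stopping, squared-error
  residual for the step) is the procedure the algorithm specifies; an
  exact-BCE gradient mode (`gradient="bce"`, zero subgradient where the
  clip is active) is available but off by default. Both directions are
  descent directions for well-behaved weights; the surrogate gradient is
  verified against central finite differences in the test suite.
* **Early stopping.** `patience` counts consecutive iterations without a
  strict validation-loss improvement; on any improvement the counter
  resets and the current weights are recorded. When the counter reaches
  patience the loop breaks and the *recorded* best-validation weights are
  returned, never the last iterate.

Every subset of size ≥ 2 gets its own weight fit (26 subsets for five
models: C(5,2)+C(5,3)+C(5,4)+C(5,5)); each subset's random initialization
uses a seed derived from the run seed and the subset index, so any single
subset's result is reproducible in isolation. The winning subset is the
one with the highest accuracy on a selection split — **validation by
default**, which is the leakage-free choice; `selection="test"` is
provided to mirror protocols that pick the winner on the test set, and
every report records which mode produced it.

## Numerical choices

* Aggregated probabilities are clipped to [0, 1] before the log loss and
  before thresholding; unconstrained weights make raw sums leave the unit
  interval, and the loss is undefined outside it.
* Classification threshold is 0.5 on the aggregated probability, with
  `p ≥ 0.5` mapping to class 1.
* ε = 1e−10 caps the per-instance loss at −ln ε ≈ 23.026 for a maximally
  confident miss.
* Grid-search ties break toward the first-listed configuration; subset
  ties on selection accuracy break by higher AUC, then smaller subset,
  then enumeration order.
* `num_iterations = 0` is a legal boundary: the initial weights are
  returned with an empty trace.
* Optimizer defaults: learning rate 0.01, 1000 iterations, patience 10 —
  conventional values for a convex-ish low-dimensional descent; all
  configurable.

## Preprocessing

All fitted statistics (imputation medians/modes, one-hot vocabularies,
min-max ranges) come from the training part only. The pipeline order is:
invalid-zero imputation → stratified split → encode/impute → normalize.

* **Invalid zeros.** Clinical columns where zero is physiologically
  impossible (e.g. blood pressure) are imputed by the median (default) or
  minimum of the column's non-zero values; an all-zero column is left
  unchanged with a warning since the statistic is undefined. Columns are
  named by the caller — no automatic detection.
* **Encoding.** One-hot with the training vocabulary; categories unseen in
  training become all-zero indicator rows. Numeric NaNs take the training
  median, categorical NaNs the training mode.
* **Normalization.** Min-max to [0, 1] per column; constant training
  columns map to 0; out-of-range test values clip. Fitting on the training
  part only is a deliberate leakage-free choice and is not claimed to match
  any particular prior protocol, some of which are silent on this point.
* **Split.** Stratified 60/20/20 train/val/test by default (a validation
  part is required by the early-stopping rule), reproducible under a seed.

## Synthetic data

The generator emulates the statistical shape of public disease-screening
tables — the regimes range from ~8% to ~53% positives with a few hundred
to a few thousand rows, mixed numeric/categorical features, missing
values, and invalid-zero artefacts:

* The positive count is **exact** — `round(n × positive_fraction)` — not a
  Bernoulli draw, so extreme imbalance is hit exactly at small n and tests
  are stable.
* Numeric features are class-conditionally Gaussian with unit variance; a
  class-1 mean shift of `class_separation` (in within-class SD units) is
  the entire signal. Categorical features are class-dependent multinomials
  whose tilt vanishes as `class_separation → 0`.
* `label_noise` flips an equal number of labels in each class (total
  ≈ the stated fraction), preserving the exact marginal count while
  decoupling the flipped instances' features from their labels.
* `corrupt` injects zeros into designated columns and blanks random cells,
  at exact rounded counts, from a corruption-specific seeded stream.

Default scenario: n = 1000, 8 numeric + 2 categorical features, 35%
positives, separation 1.5, 2% label noise — a mid-difficulty regime
comparable to a diabetes-screening table. What the generator does **not**
model: feature-level semantics and units, correlated feature blocks,
non-Gaussian tails, covariate shift between splits. Passing tests on this
data demonstrate the optimizer, search and metrics machinery; they do not
certify accuracy levels on any real clinical dataset.

## Evaluation

Accuracy, precision, recall and F1 come from confusion counts at the
threshold; precision is defined as 0 (and flagged) when nothing is
predicted positive, recall as 0 when no positives exist. The ROC curve
takes a threshold at every distinct score in descending order, anchored at
(0,0) and (1,1), tied scores sharing one step; AUC is the trapezoidal
area, which equals the probability that a random positive outscores a
random negative with ties counted half — the test suite checks this
equivalence against an independent pairwise-concordance oracle.

## Problem sizes

The test suite and the reproduction script use a 1000-instance synthetic
table (600/200/200 split), 3-fold CV, and compact per-family grids (1–2
configurations each) for end-to-end runs; oracle checks use 100 random
gradient instances (n ≤ 50, ≤ 5 models) and 200 random AUC instances.
These sizes exercise every code path, including all 26 subsets, while
keeping a full run to seconds.

## Known limitations

* Weights are unconstrained; a pathological learning rate can diverge
  (no line search or adaptive step is implemented — deliberately out of
  scope).
* The surrogate gradient is not the gradient of the monitored BCE; on
  some instances the BCE can tick up while the surrogate descends. The
  descent property asserted in tests is for the surrogate objective.
* Base-model probabilities are used uncalibrated.
* Multi-class targets are supported only through explicit binarization.
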