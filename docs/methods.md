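# Methods

## Problem setting

The package models a screening pipeline for skin-lesion classification in
which a frozen foundation model has already reduced each dermatology image
to a fixed-length embedding.  All learning happens in a small classifier
head; all uncertainty statements come from split conformal prediction; all
fairness statements come from stratifying per-sample conformal quantities
over protected attributes (sex, age band, anatomical site, cohort).  The
package never touches images: its inputs are an ID → vector JSON mapping,
a one-hot ground-truth CSV and an optional metadata CSV.

## Synthetic cohort model

`generate_cohort` draws class `c` vectors from an isotropic unit-variance
Gaussian centred at a class mean `sep · u_c`, where the `u_c` are random
orthonormal directions (QR of a Gaussian matrix) and `sep` is
`class_separation`.  All pairwise mean distances equal `sep·√2`, so a
single scalar controls attainable accuracy monotonically.  Demographics are
sampled independently of class from configurable marginals; "unknown" is a
first-class level (mirroring cohorts shipped without patient metadata).
Fairness gaps therefore must be planted explicitly:

* `noise_scale` — extra isotropic noise for one (attribute, level)
  subgroup.  This provably lowers the subgroup's attainable accuracy (the
  test suite verifies it against an oracle classifier built on noiseless
  class means), but in practice it pushes samples *off-manifold*, where a
  ReLU/batch-norm head tends to remain confident — so it degrades coverage
  for the subgroup rather than inflating its set sizes.
* `signal_attenuation` — scales the class-mean component of the subgroup's
  vectors toward the between-class overlap region.  This is the stand-in
  for lesions intrinsically harder to discriminate in one subgroup (e.g.
  lower contrast): training data of several classes genuinely co-occupy
  that region, the learned posterior is diffuse there, and prediction sets
  grow.  It is the knob used in the audit power study.
* `cohort_shift` — a constant offset along a random direction for one
  cohort, emulating covariate shift between acquisition sites.

Defaults: `embed_dim = 64`, `class_separation = 2.75`.  At that separation
the 8-class study cohort (`IMBALANCED_8CLASS_COUNTS`, ~8,000 records,
14.5:1 imbalance) puts the MLP head's top-1 test accuracy near 70% — the
difficulty regime reported for real lesion-embedding classification — while
keeping nonconformity scores well away from saturation, which matters for
the sharpness of the coverage band (see below).

What the generator does *not* emulate: the heavy-tailed, anisotropic,
cluster-within-cluster structure of real foundation-model embeddings;
label noise; correlations between demographics and class (these exist in
real dermatology data and can be added via the marginals, but are off by
default so that any fairness gap in a test is one the test planted).
Passing tests therefore demonstrate correctness of the machinery and its
statistical guarantees under exchangeability — not performance on real
patients.

## Splitting

`split_cohort` takes 20% of each class for test (floored, remainder to the
training pool), then 10% of the overall cohort for validation, then 10% of
the remaining training pool for calibration.  The calibration set is never
seen by training, checkpoint selection, or testing.  All stages draw from
one `numpy` generator seeded explicitly; per-stage seeds in the pipeline
are spawned from the master seed via `SeedSequence` and logged.

## Dynamic F1-weight sampler

Weights start at inverse class frequency (Eq. form
`w_i = (1/n_i)/Σ_j(1/n_j)`) and are refreshed every `refresh_period` epochs
(default 4) from the mean classwise F1 of the current model on the
validation set, computed over `k_folds` stratified folds (default 10; folds
re-score the fixed model, no retraining) and inverted the same way.  A
class with F1 below `f1_floor` (default 1e-3, covering exact zeros and
classes absent from validation) is floored there, keeping weights finite.

Regulation: with m = mean(w) and s = *population* SD(w) (stable for small
class counts), threshold λ = m + `lambda_multiplier`·s and minimum weight
β = m + `beta_multiplier`·s (defaults 1 and 2).  Classes with w ≥ λ — the
challenging minority classes — keep their F1 weight capped at β; classes
below λ are baseline-sampled at m; the vector is renormalised.  The source
description leaves open whether β caps the minority weights or floors the
majority ones; the cap reading is the default and the floor reading is one
config switch away (`SamplerConfig.beta_role`).

Epoch sampling draws with replacement, each record with probability
`w_label / n_label`, so the expected class share of the stream equals the
class weight exactly.

## Classifier head

`n_blocks` blocks of Linear → BatchNorm1d → ReLU → Dropout, widths halving
per block, then a final linear layer; Adam (lr 1e-3, batch 128 default) on
cross-entropy; the state with the best validation macro-F1 is restored
after training.  The full-scale profile (2048 inputs, 6 blocks, 40 epochs)
is `MLPConfig.full_scale_preset()`; tests and studies use scaled-down profiles
(16–64 inputs, 1–3 blocks, 15–30 epochs) matched to the synthetic task.
Activation, optimiser, batch size, learning rate and dropout rate are
package defaults, all config-exposed.  The implementation is pure numpy —
the per-epoch sampler hook, batch-norm/dropout blocks and best-state
checkpointing need an open training loop — with analytic gradients verified
against numerical differentiation in the test suite.

Per-class "accuracy" in the classwise tables is classwise recall (diagonal
over row sum), the convention of classwise results tables in this area.

## Conformal prediction

Nonconformity score: `s = 1 − p̂(truth)` — the minimal concrete reading of
"deviation between predicted and true labels".  Calibration threshold: the
`⌈(n+1)(1−α)⌉`-th smallest of n calibration scores, the standard
finite-sample correction; the rank is clamped to [1, n+1], rank n+1 (α
small) giving q̂ = +∞ (all sets are the full label space) and α = 1 giving
the minimum score.  A label joins the set iff `1 − p̂(label) ≤ q̂`; entries
are ordered by descending raw probability (ties broken by label index),
and the reported per-label confidence is the raw probability, not
renormalised within the set.

Empty sets: the pure procedure can return one.  For reporting, the package
substitutes the argmax singleton (a clinician-facing set should never be
empty); this deviation is toggleable (`allow_empty`), and every coverage
*measurement* in the studies and tests uses the strict procedure, because
the fallback adds sets that contain the truth whenever the argmax is
correct and thereby pushes empirical coverage above the
`1 − α + 1/(n+1)` upper band.

ECE/MCE use 10 equal-width bins by default on the per-set top-label
confidence against set correctness (truth ∈ set); ECE is the
sample-weighted mean absolute gap over nonempty bins, MCE the maximum.

## Fairness audit

A2 accuracy counts, per class, test samples whose truth is among the two
most probable labels *within their prediction set* (a singleton set has
only rank 1), over all test samples of the class; empty cells are NaN,
never zero.  Age bands are <30, [30, 60), ≥60.  The region table ranks
anatomical sites per class among top-2-correct samples, so per-class
percentages sum to 100 when all sites are known.  Group differences in
mean set size are tested with a two-sided permutation test (default 2,000
permutations, add-one p-value).

## Study conditions and numerical choices

* Coverage study (the headline check): 20 replicates of the 8-class study
  cohort; n_cal = 500, α = 0.2; strict sets; mean coverage compared to
  [0.8 − 3σ̂, 0.8 + 1/501 + 3σ̂] with σ̂ the Monte-Carlo standard error
  across replicates.  A 60-replicate run gives 0.8023 ± 0.0027, matching
  the theoretical band [0.800, 0.802].
* Sampler efficacy: 4 classes (1200/900/600/80), separation 2.0, embed_dim
  16 — a regime where the plain head essentially ignores the rare class —
  paired seeds with/without the sampler, 5 replicates, comparing mean
  minority recall.
* Audit power: 4 classes (2100/1500/900/450), separation 4.0, attenuation
  0.25 on sex = female; detection = affected group's mean set size larger,
  20 replicates.  Specificity: same cohort without the effect, permutation
  p > 0.01 at each of 5 seeds.
* All replicate seeds are spawned from one master seed; every stochastic
  component takes an explicit seed, and the end-to-end pipeline is
  byte-reproducible given the master seed.

## Known limitations

* The marginal coverage guarantee is exactly that — marginal.  Subgroup
  (conditional) coverage can be below 1 − α for a disadvantaged subgroup;
  the audit measures and reports such gaps but class- or group-conditional
  (Mondrian) calibration is out of scope.
* The guarantee assumes calibration/test exchangeability; under cohort
  shift (`cohort_shift > 0`) calibrating on one cohort and testing on the
  other voids it, which is a feature for audit experiments, not a bug.
* Nonconformity is the simple `1 − p̂(truth)` score; adaptive/cumulative
  scores that improve conditional coverage are not implemented.
* The numpy head trains on CPU and is sized for embedding inputs, not as a
  general deep-learning stack.
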