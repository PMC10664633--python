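# Methods

## Model overview

`ddafuse` predicts drug–disease associations from heterogeneous
similarity evidence. Its working assumption is that drugs similar
across several complementary views (chemical structure, side effects,
targets) tend to treat similar diseases, and that a fused similarity
matrix is a stronger predictor than any single view. The pipeline is:
per-view cosine similarity → similarity network fusion (SNF) → pair
feature table → SMOTE balancing → deep binary classifier →
cross-validated evaluation and ranking experiments.

## Cosine similarity

Profiles are strictly binary entity × feature matrices; the similarity
of two entities is the cosine of the angle between their rows, which
for 0/1 vectors lies in [0, 1] and ignores shared absent features — the
right behaviour for sparse fingerprints. Two conventions close the
gaps the formula leaves open:

* an all-zero profile row has no direction; its similarity to every
  other entity is defined as 0 (no evidence), and 1 to itself;
* the diagonal is forced to exactly 1 rather than computed, so no float
  jitter enters the fusion step.

## Similarity network fusion

SNF consumes ≥ 2 similarity matrices over the same entities. Each view
`v` is normalized two ways:

* full kernel `P_v`: `P(i,j) = W(i,j) / (2 Σ_{k≠i} W(i,k))` off the
  diagonal and `P(i,i) = 1/2`, making every row sum to 1 while keeping
  half the mass on self. Rows with zero off-diagonal mass (isolated
  entities) become identity rows and are logged.
* KNN local kernel `S_v`: each row is restricted to its K most similar
  other entities (ties broken by ascending index, for determinism) and
  renormalized. Local neighbourhoods are the most reliable part of a
  noisy similarity matrix, so they drive the diffusion.

The cross-diffusion update is
`P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ`, followed by symmetrization and —
by default — re-application of the full-kernel normalization (keeps the
row-stochastic structure and prevents drift; a config flag disables the
per-iteration renormalization). After `T` iterations the fused matrix
is the average of the per-view status matrices, symmetrized. A single
view degenerates to its normalized, symmetrized form.

Defaults `K = 20` (clamped to m−1 for small problems) and `T = 20` are
the values customary in the SNF literature; both are configurable, and
an optional `convergence_tol` stops early once `max |ΔP|` falls below
it (the per-iteration deltas are logged). An optional `rescale` flag
(off by default) divides the fused matrix by its maximum entry so its
values lie in [0, 1] before being merged with the binary labels; the
classifier is scale-tolerant, so this is cosmetic.

The implementation is vectorized; the test suite checks it against an
independent loop-based implementation of the same update rules to
1e-10 on random multi-view instances.

## Pair table, balancing, classifier

The merged table F enumerates pairs drug-major; row (i, j) carries
label Y(i, j) and features `[UDRS(i,·), UDIS(j,·)]` (m + n values).
The ID columns are metadata only — training on them would leak row
identity.

SMOTE lifts the minority class to a balance rate (minority/majority
ratio) of 0.9 by default. The number of synthetic rows is
`ceil(ratio · n_majority) − n_minority`, with the ceiling computed with
a 1e-9 slack so decimal ratios behave as written in exact arithmetic
(naively, `ceil(0.9 × 500)` evaluates to 451 in binary floating
point). Each synthetic point interpolates a uniformly drawn minority
row toward one of its k = 5 nearest minority neighbours (Euclidean
metric in the feature space, ties by index) with λ ~ U(0, 1). The
minority class is detected from the counts, not hard-coded, because
synthetic datasets can be short on either class. Balancing runs inside
each training fold only; balancing before the split would place
synthetic neighbours of test points into training, inflating every
metric.

The classifier is a dense stack — input → 5 × (300 rectified units +
dropout 0.3) → 1 sigmoid unit — trained with binary cross-entropy and
Nadam (lr 1e-3, β₁ 0.9, β₂ 0.999) at batch size 64. These
hyperparameters are the published configuration for this architecture
family and are all exposed in `NetworkConfig`. The hidden activation
(rectifier) and the 0.5 decision threshold are conventional choices
where the configuration is otherwise silent; a `conv1d` variant
(one convolution + max-pooling block before the dense stack) is kept
for experiments with a convolutional front end. The network,
backpropagation (verified against finite differences in the tests) and
optimizer run directly on numpy arrays, so training is
bit-deterministic for a fixed seed on a fixed platform. The default
200 epochs suit full-scale runs; the desk-scale experiments below use
30, which this fixture already converges well within.

## Evaluation

Confusion counts use `score ≥ threshold` as the positive call;
accuracy, precision = TP/(TP+FP), recall = TP/(TP+FN) and the F1
harmonic mean follow, with 0 substituted when a denominator vanishes.
ROC area is the trapezoidal area over all thresholds (equal, by the
Mann–Whitney identity, to the fraction of correctly ordered
positive–negative pairs — the tests assert this against a pair-counting
oracle); PR area uses the step-wise average-precision rule, which does
not over-interpolate between recall levels.

Cross-validation folds split the (drug, disease) pairs — the table's
rows. Each round reshuffles the folds with a fresh derived seed;
aggregate values are means over folds with their dispersion. A
drug-disjoint split is deliberately not the default: the pair-level
split matches the protocol this pipeline is normally reported under.

The new-drug experiment takes every drug with exactly one known
association, removes that association, and asks whether the model
ranks the withheld disease first among all n candidates (ties by
ascending index). The default `shared` mode trains one model with all
cohort labels removed; `per_drug` retrains per drug. A `score_matrix`
argument bypasses training entirely and ranks from given scores — used
for the ground-truth-affinity oracle and the random baseline (success
rate 1/n) in the tests.

## Synthetic data generator

The generator emulates the structure the method exploits, at toy
scale: drugs belong to G groups and diseases to H groups (round-robin
assignment); each group has a random binary prototype per view and
entities inherit it with independent per-bit flip probability ε; a
random G × H compatibility table decides which cells of Y are enriched
(association probability `p_hi` = 0.9) versus background (`p_lo` =
0.02). The per-cell probabilities are returned as the ground-truth
affinity matrix. The default view widths (64/48/32 drug-side, 48/32
disease-side) differ per view so shape bugs surface. A
`singleton_fraction` (default 0.1) of drugs is post-processed to keep
exactly one association — their highest-affinity disease, ties by
index — guaranteeing a populated new-drug cohort.

The documented fixture is m = 60, n = 40, G = H = 4, ε = 0.05, seed 7.
Under these conditions the within-group cosine similarity exceeds the
between-group similarity by a wide margin, and fivefold CV recovers
the planted signal with mean AUROC well above 0.85 while permuted
labels land near 0.5.

What the generator does **not** emulate: realistic fingerprint
sparsity and feature correlation, correlated views, graded (more than
two-level) affinities, or the marginal statistics of curated
benchmarks. Consequences worth knowing:

* passing tests show the pipeline recovers planted block structure
  without leakage; they do not certify performance on real data;
* because all compatible diseases of a drug share the same affinity
  level, the *model-based* new-drug top-1 rate is close to the
  within-block chance level (~H/n per drug): the model has no signal to
  order diseases within a compatible block, only to find the block.
  The oracle- and random-score controls, which have exact expected
  values, are what the tests assert.

## Problem sizes and numerical choices

The test suite and the acceptance script run the fixture at 2 400
pairs with 30 training epochs per fold — sizes chosen so the planted
signal is comfortably recoverable while a full run stays in the
minutes range on one CPU. Determinism: every stochastic step (data
generation, fold shuffling, SMOTE draws, weight init, batch order,
dropout masks) draws from a named seed; identical configs reproduce
all artifacts byte for byte. Similarity matrices are serialized at 12
significant digits, which round-trips within 1e-12. Degenerate inputs
are handled explicitly rather than propagated: all-zero profile rows
(similarity 0), isolated entities in SNF (identity rows + warning),
empty minority class (error), single-class training tables (error),
zero-denominator metrics (defined as 0).

## Known limitations

* No drug-disjoint or disease-disjoint evaluation by default (provided
  behind a flag only); pair-level CV shares entities between train and
  test folds, which is the standard but optimistic protocol.
* SMOTE interpolates in the full m+n feature space; for very large m·n
  the pairwise-distance search grows quadratically in the minority
  count.
* The classifier trains on CPU; no GPU path and no hyperparameter
  search are provided.
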