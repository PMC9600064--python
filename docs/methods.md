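# Methods

This note documents the model, its parameters, the numerical choices made
where the design was genuinely open, and what the synthetic fixtures do
and do not establish.

## Pipeline overview

One epoch (a 1-D EEG window, ≥ 512 samples for the default 5 levels) is
mapped to 10,960 features; a labeled epoch set then passes through a
three-stage feature selector and a cross-validated cubic-SVM evaluation.
All randomness (fold assignment, synthetic data) derives from one integer
seed; repeated runs of the same configuration produce byte-identical
artifacts.

## Pooling decomposition

Non-overlapping pairs `(x_i, x_{i+1})` are reduced by four statistics:
maximum (the level-update), average (M1), absolute average `|mean|` (M2),
and absolute maximum `max(|x_i|,|x_{i+1}|)` (M3). Decisions:

- M1/M2/M3 follow the operational definitions above; using several
  pooling statistics side-by-side counters the routing bias any single
  pooling has (max pooling alone only propagates peaks).
- "Absolute average" is the absolute value of the pair mean, not the mean
  of absolute values; with the companion M3 carrying magnitude
  information, `|mean|` is the natural reading of the name.
- A trailing unpaired sample of an odd-length signal is discarded.
  Padding would inject an artificial amplitude into downstream
  histograms; dropping one sample out of ≥ 512 is negligible.
- All four operators are positively homogeneous: `pool(c·x) = c·pool(x)`
  for `c > 0`. Combined with the order-based texture operator this makes
  all textural coordinates invariant to positive rescaling of the input
  (amplifier gain, unit changes).

## L-tetrolet operator

Sliding 16-sample windows (stride 1) are arranged **row-major** into a
4×4 matrix; two L-tetromino templates assign each cell to one of the
roles a/b/c/d (four cells per role, each template a permutation of all 16
cells — asserted at construction). Eight comparisons per template
(`a_k ≥ c_k`, then `b_k ≥ d_k`) give an 8-bit code, bit `k` weighing
`2^(k−1)`; ties produce a 1, so a constant window codes as 255 in both
templates. Histograms are raw counts over codes 0–255 (hist1 of P1,
then hist2 of P2, 512 values); each histogram sums to `L − 15`.

The row-major fill order is a convention frozen here (the window-to-matrix
correspondence admits several readings); every golden value in the test
suite was computed with an independent brute-force walker over the role
tables, and the vectorized implementation is checked against that walker
on 1,000 random windows.

## Statistical moments

18 summaries per vector, applied both to each (decomposed) signal and to
its 512-length tetrolet vector. Entries 13–15 duplicate entries 9/4/2;
the duplicates are kept so the published vector length (18) and the
downstream layout stay fixed — min-max normalization renders duplicated
columns harmless, and the threshold stage would remove them only if
constant. The entropy-type entries (12, 16, 18) operate on the
normalized energy distribution `p_j = x_j²/Σx²` (the standard choice for
log-energy/Shannon entropy of a signal when no probability model is
given), with natural logarithm, `0·log 0 = 0`, zero terms skipped in the
log-energy sum, and an all-zero vector yielding 0 by convention.

## Multilevel layout

Per level: `[raw | M1 | M2 | M3]`, per signal:
`[tetrolet(512) | moments(signal)(18) | moments(tetrolet)(18)]`, levels
concatenated in order — 2,192 per level, 10,960 for 5 levels. The layout
is versioned (`tetrosleep-v1`) in the persisted feature header because
selected-feature indices are only meaningful relative to it. The minimum
input length is enforced as `32·2^(levels−1)` (512 for five levels),
strictly enough that every pooled branch at every level hosts at least
one 16-sample window; 30-s epochs at ≥ 100 Hz always qualify.

## TSRFINCA

1. **Normalization**: column-wise `(x − min)/(max − min)`; constant
   columns map to 0 (0/0 guard).
2. **Threshold**: keep columns with positive sum; with threshold 0 this
   removes exactly the constant columns.
3. **ReliefF**: exhaustive multiclass ReliefF, k = 10 nearest
   hits/misses, Manhattan distance, per-feature diffs normalized by the
   feature range, miss classes weighted by `P(c)/(1 − P(class(i)))`;
   strictly positive weights survive. Exhaustive reference instances
   (no sampling) remove the only stochastic element, making the stage
   deterministic without a seed.
4. **INCA**: diagonal NCA computes one relevance weight per feature
   (see below), computed once, not re-fit per candidate size; features
   are ranked by squared weight (stable sort, so ties keep column
   order) and each top-k subset for k in [100, 1000] is scored by the
   10-fold cross-validated misclassification rate of the cubic SVM.
   The minimum-loss k wins; ties go to the smallest k (cheapest model).
   If fewer features survive than the bounds require, the bounds clamp
   to the available count with a logged warning.

The loss sweep uses an incrementally updated linear Gram matrix and a
precomputed polynomial kernel `(1 + G_k)³`, which is algebraically
identical to refitting the cubic SVM on the top-k columns but avoids
recomputing k dot products per candidate; the equivalence to the direct
SVM route is asserted in the tests.

### Diagonal NCA

Weights `w` parameterize the metric `D_ij = Σ_r w_r² |x_ir − x_jr|`; the
objective is the expected leave-one-out soft-neighbor accuracy
`Σ_i Σ_{j≠i, y_j=y_i} p_ij − λ‖w‖²` with
`p_ij ∝ exp(−D_ij)`, maximized with L-BFGS. Defaults: λ = 1/n_obs,
gradient tolerance 1e−6, iteration cap 50, float32 chunked tensors for
the O(n²d) gradient (sums accumulated in float64).

Initialization matters and is the one non-obvious numerical choice: with
thousands of features the unweighted distances are O(10³), the softmax
saturates, the NCA term's gradient vanishes, and the optimizer would be
steered by the regularizer alone (we observed exactly this collapse —
all weights driven to ~0, i.e. an arbitrary ranking). Weights therefore
start uniform at `1/√D̄`, where `D̄` is the mean unweighted pairwise
Manhattan distance (computed exactly in O(n log n) per feature via the
sorted-prefix identity), which places the initial mean distance at 1 —
inside the responsive region of the softmax. The optimization has no
random element, so determinism holds trivially.

## Classifier and metrics

Cubic SVM: kernel `(1 + x·y)³` (inhomogeneous third-degree polynomial,
kernel scale 1, offset 1), box constraint C = 1, one-vs-one multiclass,
seeded stratified 10-fold cross-validation; inputs are the min-max
normalized selected features. Test predictions are pooled across folds
into one confusion matrix. All six metrics use macro (unweighted
per-class) averaging, appropriate for balanced designs: accuracy,
macro F1, average (macro) precision, geometric mean of per-class
recalls, sensitivity (macro recall), specificity (macro one-vs-rest
true-negative rate). A never-predicted class contributes precision 0
with a logged warning rather than an error. Note that on a balanced
dataset macro sensitivity equals accuracy by construction; published
sleep-staging tables that report them as differing use some other,
usually unstated, averaging.

The optional classifier-comparison harness runs DT, LD, NB, linear /
quadratic / cubic SVM, kNN (k = 10) and bagged trees (30 trees) under
identical folds.

## Synthetic fixtures

Each stage is a sum of fixed-frequency sinusoids with seeded random
phases plus unit-variance 1/f noise, 30 s at 128 Hz, balanced classes:
W 10 Hz (+20 Hz harmonic), S1 6 Hz, S2 13 Hz (sigma band), S3 2.5 Hz,
S4 1 Hz high-amplitude delta, REM mixed 5 + 20 Hz. Sinusoid amplitudes
(0.2–1.6) sit at or below the noise standard deviation, so no single
amplitude summary separates the stages, while the spectral structure is
recoverable by the textural pipeline. Epochs are deterministic given
`(seed, class, index)`.

The generator emulates *balanced, stationary, artifact-free* band-limited
oscillations. It does not model inter-subject variability, EMG/EOG
contamination, stage transitions inside an epoch, or class imbalance —
so a green end-to-end test establishes that the pipeline recovers
planted spectral class structure far above chance on clean data, not
that it attains any particular accuracy on clinical recordings. On the
default fixtures (50 epochs per stage) the pipeline reaches 100%
cross-validated accuracy with label-shuffled controls at chance;
clinical EEG is far harder.

## EDF handling

A minimal 16-bit EDF codec (ASCII header, interleaved int16 records) is
built in; physical scaling uses the per-channel min/max, so a round trip
is exact to one quantization step of the amplitude span / 65,535. Stage
labels come from a plain two-column sidecar (`onset_seconds stage`);
R&K dialects (`Sleep stage 1`, `N1`, `S1`, …) are normalized by a
mapping table, MT/unknown labels are dropped with a warning. Epochs are
annotation-aligned (one per labeled 30-s window), never free-running. A
missing bipolar channel (e.g. `F4-C4`) is derived as the difference of
its referenced electrodes when both are present at equal sampling rates.

## Known limitations

- The O(n²·d) NCA gradient dominates the runtime (minutes at 300 epochs
  × 10⁴ features on one CPU); the iteration cap (50) bounds this at a
  small cost in final-weight precision.
- ReliefF and NCA hyperparameters (neighbors, λ, tolerances) follow
  common defaults rather than a tuned study; the selector's output size
  is sensitive to them in the expected direction (fewer neighbors →
  noisier weights).
- The cubic kernel with scale 1 on hundreds of min-max features yields
  very large kernel values; libsvm copes, but users feeding substantially
  wider selected sets may prefer rescaling inputs.
- The EDF codec intentionally implements only the classic EDF subset
  (no EDF+ embedded annotations, no discontinuous records).
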