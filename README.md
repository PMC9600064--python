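# tetrosleep

Six-class sleep-stage classification of 30-second EEG epochs with
handcrafted textural features. The package is aimed at researchers who
want a transparent, shallow-learning baseline for polysomnography epoch
classification: every feature is an explicit, inspectable statistic of
the signal, selection is traceable feature-by-feature, and the whole
pipeline runs in minutes on one CPU.

## The method

An epoch `x` (one labeled 30-s window of a single EEG channel, any
sampling rate with at least 512 samples) is processed in three phases:

**1. Multilevel feature generation.** At each of 5 levels the current
signal is decomposed by non-overlapping pairwise pooling into three
companions — average `M1_j = (x_i + x_{i+1})/2`, absolute average
`M2 = |M1|`, and absolute maximum `M3_j = max(|x_i|, |x_{i+1}|)` — and
each of the four signals (raw, M1, M2, M3) contributes 548 features:

- 512 **L-tetrolet** counts: every sliding 16-sample window is arranged
  row-major as a 4×4 matrix; two L-shaped tetromino templates partition
  its cells into roles a/b/c/d and eight signum comparisons
  `S(p,q) = 1 if p−q ≥ 0` produce an 8-bit code per template
  (bit k weighs `2^(k−1)`). The two 256-bin code histograms are the
  textural block.
- 18 statistical moments of the signal and the same 18 moments of its
  tetrolet vector (mean, extremes, median, dispersion, energy, and
  entropy-type features on `p_j = x_j²/Σx²`).

The level signal is then halved with maximum pooling
`D_j = max(x_i, x_{i+1})` and the procedure repeats, giving
5 × 4 × 548 = **10,960 features per epoch**.

**2. TSRFINCA selection.** Columns are min-max normalized; constant
columns (sum ≤ 0 after normalization) are dropped; multiclass ReliefF
keeps only strictly positive-weight features; diagonal NCA ranks the
survivors once and the top-k subsets for k = 100…1000 (901 candidates)
are each scored with the 10-fold cross-validated misclassification rate
of the cubic SVM. The minimum-loss subset wins (smallest k on ties).

**3. Evaluation.** A cubic SVM (kernel `(1 + x·y)³`, C = 1, one-vs-one)
under seeded stratified 10-fold cross-validation; fold-pooled confusion
matrix and six macro-averaged metrics: accuracy, F1-score, average
precision, geometric mean of recalls, sensitivity, specificity.

Real recordings are read from EDF files (a built-in minimal 16-bit EDF
codec; bipolar channels such as `F4-C4` are derived from referenced
electrodes when absent) with a two-column `onset_seconds stage` sidecar;
a seeded synthetic generator emulates balanced six-stage datasets of
band-limited oscillations over 1/f noise so the whole pipeline is
testable without any data download.

## Worked example

```sh
tetrosleep -v run --out demo_out --seed 1 --n-per-class 20
```

runs the full pipeline on 120 synthetic epochs (20 per stage, 128 Hz,
30 s) and prints:

```
       REM   S1   S2   S3   S4    W
  REM   20    0    0    0    0    0
   S1    0   20    0    0    0    0
   S2    0    0   20    0    0    0
   S3    0    0    0   20    0    0
   S4    0    0    0    0   20    0
    W    0    0    0    0    0   20
accuracy 100.00% with 100 selected features (k=100)
```

Rows are true stages (alphabetical), columns predictions, pooled over
the 10 test folds: all 120 epochs are staged correctly — the synthetic
stages are spectrally well separated — and the selector kept 100 of
the 10,960 features (the loss curve is already at its minimum at the
smallest candidate size). On label-shuffled controls the same protocol
stays at chance (≈ 17%). `demo_out/` holds the feature matrix
(`features.features.csv` + labels + JSON header), the selection trace
(`trace.json`, `loss_curve.csv`) and the evaluation report
(`report.json`, `confusion.txt`, `fold_accuracies.csv`). The same
stages are available piecewise as `synth`, `extract`, `select` and
`classify` subcommands, and programmatically via
`tetrosleep.run_pipeline(PipelineConfig(...))`.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it generates the default balanced six-class synthetic dataset
(50 epochs per stage), executes extraction, TSRFINCA selection and the
cross-validated cubic-SVM evaluation, and writes the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Scope

The package classifies single-channel epoch signals; it does not
download or curate polysomnography databases, model EMG/EOG artifacts,
or perform real-time scoring. See `docs/methods.md` for modeling
assumptions, parameter defaults and known limitations.
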