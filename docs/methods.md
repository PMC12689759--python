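# Methods

## The model

`avehybrid` implements a hybrid autoencoder / variational-autoencoder
("AVE") for unsupervised anomaly detection on real-valued tabular data.
Two encoder branches read the same input row `x ∈ R^d`:

- a **deterministic branch** — a stack of affine maps with ReLU
  activations producing a latent `z₁ ∈ R^L`;
- a **variational branch** — a ReLU trunk followed by two parallel linear
  heads producing a mean `μ` and a log-variance `σ` of the approximate
  posterior, from which a stochastic latent is drawn by the
  reparameterization trick

      z₂ = μ + e^σ · ε,   ε ~ N(0, I).

The two latents are fused — elementwise average by default, with a
trainable convex weight or concatenation as alternatives — and a **single
shared decoder** (mirrored ReLU stack, sigmoid output head) reconstructs
the row. Training minimizes

    total = MSE(x, x̂) + λ · KL,      KL = −½ · mean(σ − μ² − e^σ + 1),

with λ = 0.1 by default, plus an explicit ℓ2 penalty (λ₂ = 0.001) on the
weight matrices. The KL term is the per-entry mean of the closed-form
divergence KL(N(μ, e^σ) ‖ N(0, 1)), so it is zero exactly at the
standard-normal posterior and positive elsewhere.

**Reparameterization variants.** The default sampler multiplies ε by
`e^σ`, i.e. it exponentiates the whole log-variance; with σ read as
log-variance (the reading that makes the KL formula above the standard
Gaussian KL) the conventional sampler would use `e^{σ/2}`. Both are
exposed (`reparam_variant="paper" | "std"`); the first is the default.
In practice the two differ only in the scale the `σ` head learns.

**Ablations.** `branch="ae_only"` drops the variational encoder, the
sampler, and the KL term (reducing the model to a plain MSE autoencoder —
verified in the test suite against an independently coded AE trainer,
epoch by epoch); `branch="vae_only"` drops the deterministic encoder.

## Detection pipeline

1. optional feature selection (identity by default; variance threshold
   available),
2. stratified 60/40 train/test split (seeded),
3. MinMax scaling fitted on the **training rows only**; constant features
   map to 0; test values are not clipped, so unseen extremes legitimately
   inflate reconstruction error,
4. the model is trained on the **normal** training rows only (label 0),
5. per-row anomaly score = mean squared reconstruction error with zero
   latent noise (ε = 0), so scoring is deterministic,
6. **dynamic threshold**: with contamination rate `c` (the dataset outlier
   fraction divided by 3, or a user override) and `N` test rows, the
   threshold is the `(N−k)`-th ascending order statistic of the scores,
   `k = ⌊N·c⌋`; rows strictly above it are flagged. Ties at the threshold
   are not flagged; with all-distinct scores exactly `k` rows are flagged.
   The `k = 0` case thresholds at the maximum (nothing flagged). An
   alternative mode derives the threshold from training-set scores for
   deployments without a labeled test pool.

The contamination estimate uses the full dataset's labels (the benchmark
convention for labeled outlier-detection suites); the override exists
because that rule leaks label information in a true deployment.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, eps = 1e-8), batch size 64, learning rate
1e-4, at most 100 epochs, early stopping with patience 5 on a seeded 10%
validation slice of the normal training rows, monitored on the total loss
with best-epoch weight restoration. Validation forward passes use ε = 0 so
the monitor is deterministic; per-batch training noise comes from the run
seed. The last incomplete batch is kept; batch order reshuffles each
epoch. Everything — initialization (Glorot uniform), split, batch order,
noise — is a pure function of (data, model seed, train seed). The network
and its backpropagation are implemented directly in numpy; gradients are
validated against central finite differences (relative error < 1e-4) for
every branch/fusion combination.

## Default architecture

Hidden widths (64, 32), latent `L = max(2, min(32, ⌈d/4⌉))` shared by both
branches (required for averaging), all overridable. These sizes train in
seconds on a single CPU core at the benchmark dimensionalities while
leaving the bottleneck narrow enough that anomalies reconstruct poorly.

## Evaluation

Outliers are the positive class. Precision = TP/(TP+FP), TPR = TP/(TP+FN),
FPR = FP/(FP+TN); degenerate denominators return 0 with a counted warning
rather than raising, so seed sweeps never crash. ROC-AUC is computed from
the continuous scores (ties count ½; equal to the Mann–Whitney pair
statistic, which the test suite checks exhaustively on all two-class label
patterns of length 8). Benchmark-style numbers average 10 independent
trials; trial `t` uses seed `base_seed + t` for split, initialization,
noise, and label flips.

## Experiment harness

- **KL sweep**: λ ∈ {0.01, 0.05, 0.10, 0.20, 0.50} × fusion ∈ {averaged,
  weighted, concatenated}; cells hold trial-mean precision and ROC-AUC,
  averaged over trials within a dataset and then across datasets. Each
  column carries an overall average and a Δ footer — the absolute range
  (max − min) of the column expressed in percentage points.
- **Label-noise robustness**: before normal-filtering, ⌊ρ · #training
  anomalies⌋ anomaly labels are flipped to 0 (seeded, per trial), for
  ρ ∈ {0.00, 0.05, 0.10}, so mislabeled anomalies genuinely contaminate
  the training pool. The same Δ footer applies.

## Synthetic data

`generate_synthetic` emulates labeled outlier-detection benchmarks:
inliers from a mixture of unit-covariance Gaussian clusters, plus
`round(n · contamination)` planted outliers by one of three mechanisms
(uniform background box, a cluster displaced by `separation` inlier
standard deviations, or covariance inflated by `separation`). It does not
emulate heavy-tailed features, correlated/categorical attributes, or
locally clustered micro-anomalies, so passing recovery tests demonstrates
correctness of the pipeline, not performance on real data.

Problem sizes used by the test suite and the reproduction script, chosen
to exercise the full protocol at single-core desk scale:

- recovery suite: n = 2000, d = 10, 5% contamination, separation 8,
  5 trials — an easy regime where a correct implementation should rank
  essentially all planted outliers above the inliers (mean ROC-AUC ≥ 0.95,
  precision ≥ 0.8);
- noise suite: same generator at separation 4, 10 trials per ρ. At
  separation 8 precision saturates at 1.0 and label noise has no
  measurable effect; at separation 4 the expected qualitative pattern is
  visible — precision degrades with ρ while ROC-AUC stays nearly flat,
  because the flipped anomalies that enter training raise outlier
  reconstruction quality just enough to displace a few top-k ranks without
  perturbing the global ordering.

## Numerical choices

- BCE (available for binary data) carries the conventional leading minus
  and clamps predictions to [eps, 1−eps] at machine epsilon.
- MSE averages over all n·d elements, making the loss scale-free in d;
  per-row errors (the anomaly scores) live in the scoring module.
- The KL "mean" runs over both batch and latent dimensions (one scalar).
- Weighted fusion passes a single trainable scalar through a logistic, so
  the convex weight stays in (0, 1); averaging equals weighted fusion at
  α = 0.5 exactly (halving is exact in binary floating point).
- Checkpoints are JSON (format-versioned); equal inputs give byte-equal
  files, and loading a mismatched format version fails loudly.
- Constant features MinMax-map to 0; an all-constant dataset is rejected
  by the variance-threshold selector.

## Known limitations

- Dense feed-forward stacks only; no convolutional/sequence encoders.
- The contamination rule assumes labels (or a user-supplied rate).
- The f/3 heuristic under-flags by design (conservative); TPR is bounded
  by c·N/(#outliers) ≈ 1/3 when the label-derived rate is used.
- Single-threaded numpy training; intended for the small/medium tabular
  regime (thousands of rows, hundreds of features), not deep-learning
  scale.
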