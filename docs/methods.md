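# Methods

## Problem and pipeline

The package infers a binary cardiac condition (+1 clinically normal, −1
clinically abnormal) from a phonocardiogram and then mediates who may see
the derived data. The pipeline is: amplitude-normalized mono audio → three
global signal features → discrete AdaBoost stump ensemble → privacy gate
that either shares the raw features and inference or releases
Laplace-obfuscated features without the inference.

All stages are deterministic given their seeds; every stochastic component
(synthesis, fold shuffling, noise) takes an explicit seed.

## Features

* **f1, excess kurtosis of the squared signal.** Biased (population) moment
  estimators: `E[(y−μ)⁴]/σ⁴ − 3` with `y = x²`. A constant squared signal is
  rejected as degenerate. Reference points: 12 for Gaussian samples (y is
  χ²₁), −6/7 for uniform(−1, 1) samples. f1 is invariant to amplitude
  scaling and to circular time shifts.
* **f2, analytic-envelope maximum.** `max |x + j·H(x)|` via the FFT-based
  analytic signal. The envelope dominates |x| pointwise, so f2 ≥ max|x|;
  it scales linearly with amplitude.
* **f3, peak of the time-averaged short-time power spectrum.** Welch
  averaged periodogram: 1.0 s Hamming windows, 50 % overlap, one-sided
  density scaling, per-segment mean removal; the mean over segments is
  taken first and the max over frequency bins second (the opposite order
  would collapse to a scalar before the max). Window length is specified in
  seconds so fs is free to vary; at 2000 Hz this gives 1 Hz bins across the
  10–400 Hz heart-sound band. f3 scales with amplitude squared. The
  short-time estimator is the averaged-periodogram route; a
  correlogram-based estimate of the same quantity would differ only in
  windowing details.

No resampling or band-pass filtering is applied before extraction; the only
preprocessing is the read-time rescaling of PCM integers by the format's
full scale, which pins the amplitude-dependent features f2/f3 to a common
gain convention.

## Classifier

Discrete AdaBoost over depth-1 threshold stumps, the canonical shallow
ensemble: exact exhaustive stump search per round (candidate thresholds are
midpoints of consecutive sorted unique values; ties break to the lowest
feature index, then smallest threshold, then polarity +1), stump weight
`ρ = ½·ln((1−ε)/ε)`, multiplicative example-weight update, 100 rounds by
default. A round with weighted error ≥ 0.5 stops training; a perfect stump
is kept with the weight evaluated at ε = 1e−12 and also stops it. `sign(0)`
maps to +1 throughout.

Metrics follow the clinical convention: sensitivity is computed on the
abnormal (−1) class, specificity on the normal (+1) class. Stratified
K-fold cross-validation (default K = 5) shuffles within class with a seeded
generator and deals round-robin, so fold class proportions match the data
within one member; fold metrics are averaged unweighted.

## Privacy mechanism

The released object is the feature matrix itself, i.e. the identity query.
Per feature column of a *reference collection*:

* sensitivity `Δ = max − min` (empirical range under the identity query);
* privacy factor `ε = 3σ` (population standard deviation);
* Laplace scale `b = Δ/ε`, exact by construction.

The reference collection is the training feature matrix, not the released
batch: a single released record must not set its own noise scale, and the
calibration stays meaningful for batches of size one. Noise is independent
per cell, drawn from a per-record stream keyed by (seed, record_id), so a
release is reproducible and independent of row order.

The ε = 3σ rule ties the privacy factor to the data's dispersion. A
consequence worth stating plainly: because both Δ and σ carry the feature's
units, `b = Δ/(3σ)` is a *scale-free* number (roughly 1–3 for unimodal
data, bounded near √n/3 for heavy-tailed samples of size n), while the
noise it parameterizes is applied on the feature's own scale. Features
whose numeric class separation is small relative to this O(1) scale are
annihilated by the mechanism; features with numerically large separations
survive it. The narrative reading of ε (high ε = more randomness) inverts
the standard Laplace-mechanism relationship; the formula `b = Δ/ε` is what
is implemented, and the ε-DP density-ratio bound `p(t)/p(t+Δ) ≤ e^ε` holds
for it analytically.

**Uniqueness detection.** DBSCAN with minpts = 4 and radius 3 on
coordinates standardized to unit variance (equivalently ϖ = 3σ per
dimension; the three features live on scales differing by orders of
magnitude, so raw Euclidean distance would be dominated by one column).
Rows in no density cluster are "unique in the crowd". By default the mask
is reported only and noise is uniform; in tiered mode flagged rows receive
noise inflated by κ (default 2), implementing uniqueness-dependent
obfuscation. Uniform mode is the default because the equations define a
single ε per column; the tiered behaviour is the optional interpretation of
the uniqueness narrative.

**Gating.** Critical stakeholders always receive (features, inference).
Non-critical stakeholders receive them while P = 0; with P = 1 they receive
only the obfuscated features — the binary inference is omitted rather than
obfuscated, since a noisy bit is meaningless.

## Utility evaluation

The attacker model is model reuse: the adversary owns the ensemble trained
on raw features and applies it to whatever is released. Reported
quantities: metrics on raw vs obfuscated features; per-feature five-number
summaries and the IQR ratio; and per-feature mutual information. The MI
estimator is the plug-in sum over a joint equal-width histogram, 32 bins
per axis (capped at the batch size so the estimator stays defined for small
releases), log base 2, with bin edges spanning the pooled range of the two
inputs so that I(F;F) and I(F;F_prv) are measured on a common grid. With
shared edges, I(X;X) equals the plug-in entropy of the binned variable
exactly. MI is computed per feature marginal, not on the joint 3-D vector.
Plug-in MI on small samples is biased upward; only the inequality
I(F;F_prv) < I(F;F) is treated as meaningful, not the absolute bit counts.

## Synthetic data generator

The generator produces the structure the features respond to, not
physiology: concatenated cardiac cycles (default 70 bpm with ±20 % jitter
across records) of a Hann-enveloped S1 burst (30–100 Hz), a silent
systole, an S2 burst (60–150 Hz) and a silent diastole, over a white noise
floor, at 2000 Hz for 10 s by default (valid 5–120 s). Abnormal recordings
add band-limited (120–420 Hz) murmur noise gated to the systolic intervals
and Poisson-timed enveloped transients (default 2/s). Records are written
at a fixed gain well below full scale — peak sustained amplitudes around
0.1–0.2 — as recordings at modest input gain; amplitudes are clipped to
[−1, 1] only as a safety net.

Per record, burst amplitudes, durations, frequencies and the noise-floor
level are drawn from a "base" stream, and the pathology from a separate
stream, both keyed by the record seed; a matched normal/abnormal pair with
the same seed therefore differs only by the pathology. Class separation is
deliberately carried mainly by the envelope peak (f2: transients roughly
double it) and the broadband power the transients and murmur add (f3),
while f1 receives a smaller consistent increment on top of a large shared
record-to-record spread. This reproduces all the qualitative structure at
once: abnormal f1 stochastically dominates normal f1 (matched pairs order
correctly in ≥ 90 % of seeds), stratified 5-fold CV reaches ≈ 0.96 accuracy
on the default 100+100 dataset — high but not perfect — and no feature's
numeric class separation survives the ε = 3σ noise scales, so the trained
model collapses to chance (≈ 0.53 over 20 noise seeds) on obfuscated
releases.

What the generator does **not** emulate: real murmur morphology and timing
(pan-/late-systolic shapes, diastolic murmurs), S3/S4 sounds, sensor and
ambient noise structure, inter-patient recording-gain variation, or any
specific pathology. Passing tests therefore demonstrate that the pipeline's
mechanics and the privacy mechanism behave as specified on data with the
assumed feature structure — not clinical performance on real heart sounds,
which depends on dataset-specific feature distributions.

## Problem sizes and numerical choices

The default study dataset is 100 normal + 100 abnormal 10 s recordings
(master seed 42); evaluation splits it 70/30 with class stratification, and
noise-averaged quantities use 20 noise seeds. Closed-form feature checks
use 10⁶ samples; noise distribution checks use 10⁵–10⁶ draws; oracle
equivalence checks (DBSCAN vs density-reachability closure, single-round
boosting vs exhaustive stump search) run on 100 and 50 random instances of
up to 40 and 50 points respectively.

Degenerate inputs are errors, not silent results: constant squared signals
(f1), signals shorter than one analysis window (f3), constant reference
columns (ε would be 0), single-class training sets, classes smaller than K.
An all-zero signal is a valid input to f2/f3 (both 0). Border points in
DBSCAN reachable from several clusters are assigned by the underlying
implementation's scan order; the test oracle treats any admissible cluster
as correct.

## Known limitations

* The ε = 3σ calibration makes privacy protection scale-dependent (see
  above); numerically large, well-separated features can survive
  obfuscation. This is inherent to the rule, not to the implementation.
* No privacy-budget accounting across repeated releases of the same
  records; each release is calibrated independently.
* The attacker model is limited to reuse of the screening model; membership
  inference or reconstruction attacks are out of scope.
* Heart-sound segmentation (S1/systole/S2/diastole state tracking) is not
  performed; the features are global by design.
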