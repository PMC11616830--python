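# Methods

This note documents the models and procedures implemented in `pcgscreen`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Signal model and preprocessing

Phonocardiograms are treated as band-limited (≤ 2 kHz) non-stationary audio.
All recordings — regardless of source sampling rate — are polyphase-resampled
to a common 4 kHz and peak-normalised per recording to [-1, 1]. Normalisation
is per *recording*, not per 4 s window, so relative loudness across the windows
of one recording is preserved; this is configurable (`preprocess` is a pure
function of `SpectrogramParams`).

Windowing: 4 s segments, 1 s stride. For a recording of duration `D ≥ 4` s the
segment count is `floor((D − 4)/1) + 1` exactly (offsets 0, 1, 2, … s).
Recordings shorter than 4 s are zero-padded to a single flagged window rather
than dropped — short records are common in other public heart-sound
collections, and silently losing patients would bias patient-level metrics.

Log-mel transform: STFT with a 25 ms periodic Hann window and 10 ms hop,
**no centering**, so the frame count has the closed form
`1 + floor((n_samples − win)/hop)` = 398 frames for 4 s at 4 kHz. A triangular
mel filterbank (HTK mel scale) spans 10–2000 Hz. Power is floored at
ε = 1e-10 before `10·log10`, then each window is min-max scaled to [0, 1]
(configurable). Numerical notes:

* At the default `n_mels = 128` with a 100-sample FFT (51 bins), some low mel
  bands are narrower than one FFT bin and sit constantly at the log floor.
  This is harmless for the classifier (constant rows) and is why the
  "amplitude scaling is additive in the log domain" property is asserted on
  off-floor pixels only.
* `n_mels` is a resolution choice, not physics; desk-scale runs use 32 bands.

## Window classifier (BBRes)

A residual CNN maps one log-mel image to a single logit. Two backbones share
every structural convention:

* `resnet50` — standard Bottleneck stack (3-4-6-3, widths 64–512, expansion 4),
  7×7/2 stem with 3×3/2 max pool.
* `resnet18_lite` — a narrow BasicBlock stack (one block per stage, base width
  8 by default) with a 3×3 stem, intended for CPU-scale experiments. An
  optional average-pool layer at the model entry (`input_pool`) reduces the
  input image; desk-scale runs use `(1, 4)` on 32-band spectrograms.

The Bayesian variant inserts inverted dropout (default rate 0.2) after each
in-block ReLU activation of every residual block, plus one dropout before the
final linear layer, and keeps these layers **active at inference** while batch
normalisation stays in eval mode. T stochastic forward passes (default T = 20)
give a Monte-Carlo estimate of the posterior predictive mean and a standard
deviation used as the uncertainty signal. Exact degenerations, asserted in
tests: dropout rate 0 or T = 1 ⇒ zero MC std and numerical identity with the
deterministic baseline path; the MC mean is seed-stable at the O(1/√T) rate.

The whole network — im2col convolution, batch norm, pooling, dropout, residual
wiring, Adam, binary cross-entropy with optional inverse-class-frequency
weights — is implemented in NumPy with explicit forward/backward passes,
verified against numerical gradients and a `scipy.signal.correlate2d` oracle.
Initialisation is He-normal; a `pretrained_init` switch loads weights from a
state-dict NPZ when one is supplied. Optimiser (Adam, lr 3e-3, weight decay
1e-4), epoch count (8) and batch size (64) are package defaults, not canonical
values from any publication; they are recorded in every checkpoint.

Training contract: every window inherits its patient's binary label
(murmur task: Present ∪ Unknown = positive, the grouping used for the binary
screening analysis; configurable to Present-only). Train and validation splits
are at patient granularity and leakage raises. The best checkpoint is chosen
on deterministic validation loss.

## Aggregation and fusion

Window probabilities are combined by arithmetic mean in two stages: windows
within a recording, then recordings within a patient. The two-stage form keeps
a patient with one long recording from dominating their own score through
window count; a pooled single-stage mean is available (`mode="pooled"`). The
MC standard deviation is propagated by the same averaging.

Fusion is a gradient-boosted tree classifier (XGBoost, depth ≤ 3, ≤ 200
rounds, early stopping on a 20% seeded slice) over `[p_deep, demographics,
signal features]`. The trees are fitted with the deep score's clamped logit as
**base margin**, i.e. as residual corrections on top of the deep score. This
choice was made because plain tree fusion re-bins the continuous deep score
into plateaus, destroying ranking information near-ties; residual stacking
keeps the fused score anchored to — and continuous in — the deep score, so
fusion cannot erase the acoustic signal (asserted: fused AUC ≥ deep AUC − 0.02
over five seeds). The MC uncertainty can be added as a fusion feature behind
`include_std` (default off).

Demographic encoding follows the challenge-baseline convention: age categories
map to approximate months (Neonate 0.5, Infant 6, Child 72, Adolescent 180;
configurable), sex is one-hot (all-zero when missing), pregnancy is binary
(missing → 0). Mean imputation applies to the numeric fields (age months,
height, weight) with statistics fitted on training folds only; categorical
missingness is represented, never imputed. Signal features per recording:
time-domain moments (mean, std, skewness, kurtosis, RMS, zero-crossing rate)
and frame-wise spectral centroid, 85%-roll-off and bandwidth (magnitude-
weighted std around the centroid), each summarised as mean and std, plus the
dominant frequency of the average spectrum — 13 features, in Hz where
applicable, averaged without weights across a patient's recordings. The 85%
roll-off fraction and the exact feature list are package choices, versioned in
config.

## Evaluation protocol

* Decision rule: positive iff `score ≥ threshold` (ties positive), threshold
  0.5 unless swept.
* Per-class accuracies are recalls; FNR/FPR are computed from the confusion
  counts (`fn/(tp+fn)`, `fp/(fp+tn)`). An empty class yields NaN plus a flag,
  never a silent zero.
* AUC is the Mann-Whitney rank statistic with ties counted ½, tested against
  an exhaustive O(n²) pairwise oracle.
* Weighted accuracy takes the class-weight vector as an argument
  (`Σᵢ wᵢ·correctᵢ / Σᵢ wᵢ·totalᵢ`); the three-class challenge weights
  (5, 3, 1) ship as a config constant. The challenge's outcome *cost* metric
  is not reproduced; the reporting surface accepts any callable metric.
* Cross-validation is stratified k-fold at patient granularity (k = 10 by
  default), so grouping holds by construction; fold reports carry per-fold
  values plus mean and std.
* `balanced_subsample` equalises class counts at the minority size, without
  replacement, deterministic per seed. A seeded stratified 70/30 split utility
  supports fine-tuning protocols.
* Zero-shot transfer runs a foreign catalog through the identical
  preprocessing and fingerprints (SHA-256) every model parameter before and
  after prediction; any mutation raises. Transfer reports use the
  (overall, positive-class, negative-class) accuracy ordering.

Patients with zero usable recordings are excluded from evaluation with a
warning; the protocol defines no other place for them.

## Synthetic cohorts

The generator emulates the data *layout* and *statistics* the pipeline
assumes, not heart physiology. Each recording is a sum of: S1 and S2 damped
sinusoids (centre 50–150 Hz, 30–50 ms, heart rate 70–140 bpm, systole = 0.35
of the cycle), ambient white noise at −20 dB relative to the S1 peak, and —
for murmur-positive patients — band-limited Gaussian noise (150–400 Hz,
4th-order Butterworth) gated to systole at a configurable SNR relative to the
ambient floor (+10 dB default). "Unknown" murmur patients are generated 12 dB
quieter than "Present" ones, which is what makes the Present ∪ Unknown binary
grouping coherent in synthetic runs. Labels and demographics follow the
942-patient training population: murmur prevalence 695/68/179 (Absent /
Unknown / Present), outcome conditionals P(Abnormal | murmur) = 263/695,
43/68, 150/179, age sampled conditionally on murmur from the published
age-by-murmur contingency (over the four real age groups), heights/weights
from crude age-group anthropometry, and 13% *concurrent* age/height/weight
missingness applied as a joint mask. Durations default to 5–80 s with 1–6
auscultation sites.

What passing synthetic tests shows — and does not show: the pipeline can
recover a planted, band-localised, systole-gated acoustic difference at
realistic label imbalance, and its controls sit at chance when the association
is broken (shuffled labels) or the band is numerically absent (−200 dB SNR).
Real murmurs are not band-limited noise bursts; real recordings carry sensor,
handling and ambient artefacts the generator does not model. Synthetic results
therefore validate the *machinery*, not clinical performance.

## Desk-scale problem sizes

End-to-end experiments (tests and `scripts/acceptance.py`) use the lite
backbone on 32-band spectrograms with cohorts of 200 patients, recordings of
6–12 s at 1–2 sites, 8 training epochs and T = 20 MC passes; the chance-level
controls use 4 epochs, T = 5, no fusion, and an even train/test split averaged
over five seeds (the even split and seed averaging tighten the null-AUC
estimate, whose variance is otherwise inflated by finite-sample correlation
between permuted and true labels). Cohort label statistics keep their
population defaults throughout.

## Known limitations

* No S1/systole/S2/diastole state segmentation, denoising, or signal-quality
  assessment; windows are taken blindly across the record.
* ImageNet initialisation is supported only via a user-supplied weights file;
  all shipped results use He initialisation, so they are not directly
  comparable to transfer-learning results.
* The outcome task shares the murmur architecture and differs only in labels;
  no outcome-specific acoustic modelling is attempted.
* The NumPy network is CPU-bound; the full `resnet50` is constructible and
  correct but impractically slow to train here — it exists so that configs
  and checkpoints are portable to the full-scale architecture.
* CLI exit codes: 0 success, 1 runtime/validation failure, 2 malformed
  invocation (click's usage-error convention).
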