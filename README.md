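# pcgscreen

Heart-murmur screening from phonocardiograms (PCG): a deep multimodal pipeline
for paediatric cardiac auscultation data in the PhysioNet-challenge layout,
plus the evaluation protocol needed to study it across sites.

## Who this is for

Researchers working on automated auscultation — e.g. point-of-care murmur
pre-screening in settings where trained cardiologists are scarce — who need a
reproducible reference pipeline: from raw heart-sound WAV files and patient
metadata to patient-level screening scores, cross-validated metrics, decision
threshold analysis, and zero-shot transfer between datasets.

## The model

Each auscultation recording (up to six chest locations per patient) is
resampled to 4 kHz, peak-normalised to [-1, 1], and cut into overlapping 4 s
segments with a 1 s stride. Each segment becomes a log-mel spectrogram (25 ms
periodic Hann window, 10 ms hop, 10–2000 Hz band):

```
x(t) ──► STFT ──► mel filterbank ──► 10·log10(max(P, ε)) ──► S ∈ R^{128×398}
```

A residual CNN classifies each window. The *Bayesian* variant (BBRes) inserts
dropout inside every residual block and **keeps it active at inference**:
T stochastic forward passes give Monte-Carlo samples p₁…p_T of the
positive-class probability, approximating the posterior predictive
(MC dropout):

```
p̂ = (1/T) Σ_t p_t          (prediction)
σ̂ = std(p_1 … p_T)         (uncertainty)
```

Window scores are aggregated by arithmetic mean — windows within a recording,
then recordings within the patient. The aggregated deep score is fused with
encoded demographics (age in months, one-hot sex, pregnancy, height, weight;
mean-imputed) and audio summary features (spectral centroid / roll-off /
bandwidth statistics, time-domain moments) by an XGBoost classifier trained as
a residual correction on the deep score's logit.

Two binary tasks share the pipeline: murmur (Present ∪ Unknown vs Absent) and
clinical outcome (Abnormal vs Normal). Evaluation follows a grouped, stratified
10-fold protocol (no patient spans train and test), with balanced subsampling
for the heavily imbalanced 2016-style data, threshold sweeps of
accuracy/FPR/FNR, and a guarded zero-shot mode that verifies no parameter is
touched when a trained model meets a foreign dataset.

The network, including im2col convolution, batch normalisation, dropout,
residual blocks and Adam, is implemented in NumPy inside `pcgscreen.nn`; the
full `resnet50` (Bottleneck 3-4-6-3) and a narrow `resnet18_lite` for
desk-scale work are both available and config-identical.

A synthetic cohort generator (`pcgscreen.synthetic`) produces download-free
datasets in the same on-disk layout: damped-sinusoid S1/S2 transients, a
band-limited systolic murmur at a controllable SNR, ambient noise, and label /
demographic statistics matching the 942-patient training population (73.8%
Absent / 7.2% Unknown / 19.0% Present; outcome conditionals from the published
contingency table; ~13% concurrent metadata missingness).

## Worked example

```bash
# 1. simulate a 60-patient cohort (synthetic phonocardiograms, 2022 layout);
#    short recordings keep the demo fast — drop the sim block for full-length ones
cat > demo/sim.yaml <<'YAML'
sim: {duration_range_s: [6.0, 12.0], n_locations: [1, 2]}
YAML
pcgscreen simulate --out demo/data --n-patients 60 --seed 7 --config demo/sim.yaml

# 2. train the murmur pipeline (lite backbone config)
cat > demo/model.yaml <<'YAML'
spectrogram: {n_mels: 32}
model: {backbone: resnet18_lite, lite_width: 8, input_pool: [1, 4],
        epochs: 6, mc_passes: 20}
YAML
pcgscreen train --data demo/data --task murmur_binary \
    --out demo/model --seed 7 --config demo/model.yaml

# 3. predict and evaluate at the 0.5 decision threshold
pcgscreen predict --model demo/model --data demo/data --out demo/preds.csv
pcgscreen evaluate --predictions demo/preds.csv --data demo/data \
    --task murmur_binary --threshold 0.5
```

The final command prints a JSON report; on this 60-patient demo cohort it ends
with

```
  "acc_overall": 1.0,
  "acc_positive": 1.0,
  "acc_negative": 1.0,
  "fnr": 0.0,
  "fpr": 0.0,
  "auc": 1.0,
  ...
  "n": 60
```

`acc_positive` is the recall of the Present-or-Unknown murmur class (its
complement is the false-negative rate, the critical error for a screening
tool), `acc_negative` the recall of the Absent class, and `auc` the
threshold-free ranking quality. Training and evaluating on the same small
cohort, as here, overstates performance — it is a smoke test, not a benchmark;
use `pcgscreen crossval` for honest in-distribution numbers and
`pcgscreen zeroshot` for transfer to a foreign dataset.

## Real datasets

The loaders understand the public heart-sound collections directly:
`scan_dataset(root, schema="circor2022")` for the 2022-challenge training set
(942 patients, murmur and outcome labels in per-patient text headers) and
`schema="cinc2016"` for the 2016-challenge layout (one WAV per record plus
`REFERENCE.csv`; each record is treated as a single-recording patient).
Nothing in the test suite or the acceptance script downloads them; they are
supported for full-scale reproduction only.
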