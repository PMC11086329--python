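# ppgrehab

Tri-wavelength photoplethysmography (PPG) for stroke-rehabilitation
assessment: a synthetic signal generator, the preprocessing and vitals
stack of a finger-worn acquisition device, and an MCNN-LSTM-Attention
classifier that assigns Brunnstrom recovery stages from raw multi-channel
pulse waveforms.

## Who this is for

Researchers working on wearable PPG analytics who need a fully
reproducible, clinically-unencumbered test bed: every stage of the
pipeline — acquisition (simulated), filtering, heart-rate and SpO₂
estimation, deep-network staging, k-fold evaluation — is implemented as a
tested library with deterministic seeding, so methods can be compared
without access to patient recordings.

## The science in brief

**Signals.** A reflectance sensor records green (~527 nm), red (~660 nm)
and infrared (~880 nm) intensity at 100 Hz. The green channel is most
sensitive to superficial pulsatile blood volume and drives heart-rate
estimation; red and infrared penetrate deeper and drive oxygen saturation
through the ratio-of-ratios

```
R = (AC_red / DC_red) / (AC_ir / DC_ir),      SpO₂ = 110 − 25·R
```

**Simulator.** Each beat is a systolic Gaussian bump plus a smaller
dicrotic Gaussian bump. Impaired vascular-wall elasticity after stroke
attenuates the dicrotic wave, so the class effect is a single relative
amplitude per stage (V = 0.05, VI = 0.25, VII/healthy = 0.5). Three noise
classes are superimposed: white noise, respiration-locked baseline drift
plus slow wander, and mains interference plus sparse spike artifacts. The
red/IR scalings are solved from the inverse calibration line so the
simulator and the SpO₂ estimator are mutually consistent.

**Preprocessing.** A zero-phase Chebyshev Type II band-pass
(passband 0.5–10 Hz, stopband edges 0.2/15 Hz, 40 dB attenuation) removes
drift and high-frequency interference; residual baseline is removed by a
cubic spline through per-beat valleys. Gaussian, Savitzky–Golay and
moving-average smoothers are provided for SNR comparison.

**Classifier.** Each 5 s window (three channels, z-scored) passes through
two parallel 1-D conv branches per wavelength — a large-kernel *shallow*
branch and a small-kernel *deep* branch — whose outputs are pooled onto a
common time axis and concatenated; stacked LSTMs fuse the sequence; an
additive-attention layer pools the hidden states into one context vector
(`α = softmax(vᵀ tanh(W h_j + b))`, `C = Σ α_j h_j`); fully connected
layers with softmax output the stage. Ablations `cnn_lstm`,
`cnn_lstm_attention` and `mcnn_lstm` drop the shallow branch and/or the
attention module. The network and its backpropagation are implemented in
numpy inside the package (`ppgrehab.nn`).

**Evaluation.** 10-fold cross-validation (window- or subject-grouped)
with confusion-matrix metrics: accuracy = trace/total, and one-vs-rest
macro-averaged precision, recall and F1.

## Worked example

```python
from ppgrehab import SynthConfig, generate_dataset, estimate_vitals

cfg = SynthConfig(subjects_per_class={"V": 1, "VI": 1, "VII": 1},
                  duration_s=60.0, seed=42)
for rec in generate_dataset(cfg):
    v = estimate_vitals(rec)
    print(f"{rec.subject_id} stage {rec.stage:>3}: "
          f"HR {v.hr_bpm:6.1f} bpm, SpO2 {v.spo2_pct:5.1f} %, {v.n_beats} beats")
```

prints

```
S000 stage   V: HR   76.9 bpm, SpO2  94.6 %, 77 beats
S001 stage  VI: HR   72.3 bpm, SpO2  97.2 %, 72 beats
S002 stage VII: HR   69.8 bpm, SpO2  96.1 %, 71 beats
```

Each subject's heart rate is drawn from N(75, 8) bpm and recovered from
the filtered green channel via median inter-beat interval; SpO₂ targets
97 ± 1 % and is recovered from the red/IR ratio-of-ratios under the full
default noise load (the residual 1–2 point spread is artifact noise, not
bias — noise-free recovery is accurate to ±0.5 points).

Training and cross-validating the classifier on the package's separable
benchmark:

```python
from ppgrehab.benchmark import make_benchmark, benchmark_model_config
from ppgrehab.evaluate import crossvalidate

windows = make_benchmark(seed=0)              # 270 two-second windows
report = crossvalidate(windows, benchmark_model_config(),
                       "mcnn_lstm_attention", k=10, seed=0)
print(f"accuracy {report.accuracy:.4f}  loss {report.loss:.4f}")
# accuracy 1.0000  loss 0.0032
```

A `ppgrehab` console script exposes the same stages
(`simulate`, `preprocess`, `vitals`, `train`, `evaluate`, `compare`,
`run`); `ppgrehab run --seed 0 --out outdir` executes the whole pipeline
and writes every intermediate with a manifest of content hashes.

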