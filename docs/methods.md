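# Methods

## Signal model

A beat is modelled on its phase fraction `p ∈ [0, 1)` as the sum of two
Gaussian bumps,

```
s(p) = A · [ exp(−(p − c_s)² / 2w_s²) + d · exp(−(p − c_d)² / 2w_d²) ]
```

with systolic center `c_s = 0.3`, width `w_s = 0.08`, dicrotic center
`c_d = 0.65`, width `w_d = 0.1`. The dicrotic relative amplitude `d` is
the single class-separating quantity: stroke impairs vascular-wall
elasticity and attenuates, up to erases, the dicrotic wave, so the
defaults are `d = 0.05` (stage V), `0.25` (stage VI), `0.5` (healthy,
stage VII). Any physiologically shaped template would serve; two
Gaussians were chosen because dicrotic disappearance becomes one scalar
knob and analytic statements (unimodality at `d = 0`) stay provable.

Beats are laid down with per-beat multiplicative period jitter (default
3 %) around a subject heart rate drawn from N(75, 8) bpm. Channel
composition is `x_c(t) = DC_c + m_c · DC_c · pulse(t)` with the zero-mean
unit pulse shared across wavelengths. The green perfusion ratio
`m_green = 0.05` is the largest (superficial pulsatile sensitivity); the
infrared ratio is fixed at `m_ir = 0.02` and the red ratio is solved from
the inverse of the SpO₂ calibration, `m_red = R(SpO₂) · m_ir` with
`R = (110 − SpO₂)/25`, so a noise-free record round-trips its target
saturation through the estimator by construction. Intensity units are
arbitrary (the sensor hardware defines none); DC levels are 100/80/90
a.u. for green/red/IR.

Three noise classes (defaults in a.u., chosen to be comparable to the
~5 a.u. green AC amplitude):

* random — white Gaussian, σ = 0.5;
* low-frequency — respiration-locked sinusoid (0.25 Hz, amplitude 5)
  plus a slow random walk through 5 s spline knots at 0.3 × that
  amplitude;
* high-frequency — mains sinusoid (50 Hz, amplitude 0.5; at a 100 Hz
  sampling rate this aliases onto the Nyquist bin and is removed by the
  band-pass) and Poisson spike artifacts (0.5 s⁻¹, amplitude 10).

Randomness: one root seed; subject *k* draws from
`SeedSequence([seed, k])`, so a subject reproduces bit-identically
regardless of cohort composition.

The generator emulates amplitude relationships, beat morphology, drift
and artifact structure. It does **not** model motion-artifact templates,
vascular transmission-line dynamics, sensor quantization, or
between-class physiology beyond the dicrotic amplitude (optional
heart-rate shifts are off by default to keep one documented separability
axis). Passing tests therefore demonstrate correctness of the pipeline
and learnability of the modelled morphology difference — not clinical
performance on real recordings.

## Preprocessing

The primary filter is a Chebyshev Type II band-pass: monotone passband,
equiripple stopband. Template: passband 0.5–10 Hz (heart-rate
fundamentals 0.66–3 Hz plus harmonics), stopband edges 0.2 and 15 Hz,
40 dB stopband attenuation, ≤1 dB passband deviation; the order comes
from the standard minimum-order design (`scipy.signal.cheb2ord`). It is
applied forward–backward (`sosfiltfilt`), i.e. zero phase, so systolic
and dicrotic timing is preserved for both beat detection and the
classifier. Comparison smoothers use typical PPG values: Gaussian
σ = 0.05 s, Savitzky–Golay 0.31 s window / order 3, moving average
0.15 s.

Residual baseline is removed by a cubic spline through per-beat valley
anchors (minimum between successive systolic peaks, found on a linearly
detrended copy so a strong ramp cannot mask the beats; fixed 1 s anchors
are available as a fallback). Fewer than four anchors degrades to mean
subtraction with a logged warning.

The SNR convention is `10·log₁₀(P_in / P_out)` with periodogram power
integrated inside versus outside the 0.5–10 Hz pulse band. It is a
*relative* quality measure for comparing filters on the same record; its
absolute value depends on record content.

## Vitals

* Beats: `scipy.signal.find_peaks` with a 0.33 s refractory period
  (≤180 bpm) and an adaptive prominence threshold of 0.5 × the rolling
  2 s peak-to-peak amplitude — the 0.5 fraction rejects dicrotic waves
  (relative amplitude ≤ 0.5) at any heart rate.
* Heart rate: 60 / median inter-beat interval; the median tolerates a
  single missed or spurious peak. Fewer than two peaks yields NaN plus a
  quality flag. At 100 Hz the integer-sample quantization of beat
  positions bounds the error by about 1 bpm at 110 bpm.
* SpO₂: per 5 s window, AC is the RMS of the band-passed component in a
  narrow band (±0.25 Hz) around the cardiac fundamental located on the IR
  spectrum within 0.7–3.5 Hz, and DC is the raw window mean;
  `R = (AC_red/DC_red)/(AC_ir/DC_ir)` is medianed across windows and
  mapped through `SpO₂ = 110 − 25R` (the standard empirical
  pulse-oximetry line; slope/intercept configurable), clamped to
  [70, 100] %. Restricting AC to the pulse line leaves the ratio of a
  clean recording exactly unchanged (both channels carry the same
  waveform up to scale) while suppressing the broadband-artifact bias
  that a full-band RMS suffers.
* Paired errors against a reference instrument are reported as
  `round(|device − reference| / reference × 100)` integer percent, plus
  the maximum.

## Network

Architecture per window (3 × window_len, per-channel z-scored):

1. **Branches** (weights shared across wavelengths, so permuting the
   wavelength inputs permutes the corresponding feature blocks): shallow
   branch kernel 21, 2 layers, 16 filters; deep branch kernel 5,
   4 layers, 32 filters; ReLU and width-2 max pooling after each
   convolution. Branch outputs are max-pooled onto the shorter branch's
   time axis (adaptive segments) and concatenated along the feature axis,
   wavelength-major.
2. **LSTM**: standard non-peephole gates
   (`i, f, o = σ(·)`, `g = tanh(·)`, `C_t = f·C_{t−1} + i·g`,
   `h_t = o·tanh(C_t)`), 2 layers × 64 hidden, forget bias 1.
3. **Attention pooling**: additive scores `e_j = vᵀ tanh(W h_j + b)`
   with a single learned query — classification has one output step, so
   the general encoder–decoder alignment specializes to one softmax over
   time; `C = Σ α_j h_j`, `Σ α_j = 1` by construction.
4. **Head**: FC [64] + ReLU + dropout 0.5, linear softmax output over
   the stages.

Ablations: `cnn_lstm*` variants drop the shallow branch; `*_lstm`
variants replace attention pooling by the last hidden state.

Training: softmax cross-entropy, Adam (lr 10⁻³, batch 32, 30 epochs by
default) with cosine decay of the learning rate to 10 % of its base
value over the run — the decay lets the run settle instead of
oscillating near its optimum. Initialization, shuffling and dropout all
draw from one generator seeded by `ModelConfig.seed`, so identical
config + seed reproduces identical losses. All layers, including
backpropagation, are written in numpy; forward passes are verified
against brute-force definitions and backward passes against central
finite differences in the test suite.

Window length defaults to 5 s (500 samples at 100 Hz) — long enough for
4–9 beats, short enough to yield tens of windows per subject.

## Evaluation

Confusion matrices are oriented rows = predicted, columns = truth.
Multi-class precision/recall/F1 reduce one-vs-rest per class and
macro-average (micro and binary schemes selectable); zero-denominator
classes contribute 0 with a flag. K-fold splitting shuffles windows
(default) or whole subjects; subject grouping avoids within-subject
leakage and is recommended when enough subjects exist (window grouping
remains the default because small cohorts cannot stratify 10 folds
subject-wise). Reported loss is the final-epoch validation cross-entropy;
aggregates are unweighted fold means and confusion matrices are summed so
each window counts exactly once.

## Benchmark scale

The standard separable benchmark uses 3 subjects per class × 60 s records
× 2 s windows (270 windows) and a reduced network (shallow 15/1/8, deep
5/2/16, pool 3, LSTM 32 × 1, attention 32, FC [32], dropout 0.3,
15 epochs, batch 16, lr 3·10⁻³). These sizes are the package's desk-scale
choice: a full 10-fold cross-validation completes in well under a minute
while leaving the three-class problem non-trivial under its noise floor.

## Known limitations

* The classifier's perfect benchmark accuracy reflects the simulator's
  single clean separability axis; real recordings add inter-subject
  morphology variation the generator does not model.
* SpO₂ under heavy spike artifacts retains a 1–2 point downward spread;
  only the noise-free round trip is accurate to ±0.5 points.
* Heart-rate precision is limited by integer-sample beat positions
  (~1 bpm at 110 bpm at 100 Hz); sub-sample peak interpolation is not
  implemented.
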