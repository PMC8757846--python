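# Methods

This note documents the models, the defaults and the reasoning behind the
open design choices in `idpcg`, and what the synthetic-data experiments
do and do not demonstrate.

## The inverse-delayed neuron model

The ID model couples each neuron's internal state `u_i` to its output
`x_i` through the *inverse* of the sigmoid rather than the sigmoid
itself: `tau_x dx/dt = u - g(x)` with `g(x) = arctanh(x) - K x`.  For
`K = 0` the output nullcline `u = arctanh(x)` is monotone and the model
behaves like a Hopfield network with output delay; for
`K > 1 + tau_x/tau` the nullcline is N-shaped and an interval
`|x| < sqrt(1 - 1/(K - tau_x/tau))` has `phi = g'(x) + tau_x/tau < 0`
(negative resistance), where the Lyapunov energy rate
`dE/dt = -sum phi_i (dx_i/dt)^2` turns positive and the state is pushed
out of energy minima.

Choices and conventions:

* **Bias term.** The internal-state equation includes `+h_i`; the energy
  gets the matching `-(1/tau) sum h_i x_i`.  Setting `h = 0` recovers the
  bias-free form.
* **Self-connections** are fixed at zero (`a_ii = 0`) to avoid
  hysteresis; the `Synapses` container rejects nonzero diagonals.
* **Defaults** `tau = 1`, `tau_x = 0.1` satisfy the required time-scale
  separation `tau_x << tau` while keeping the stiffness ratio mild
  enough for explicit integration.
* **Integrator**: fixed-step RK4 with `dt = tau_x/20` by default and a
  hard guard `dt <= tau_x/10`.  Deterministic, and its 4th-order
  convergence is asserted in the tests.  Outputs are re-clamped into
  `[-1+eps, 1-eps]` after every step.
* **Energy evaluation** uses the closed form
  `∫_0^x g = x·arctanh(x) + ln(1-x²)/2 - Kx²/2`, verified against
  adaptive quadrature.
* **Tie-break**: `phi = 0` counts as positive resistance (the energy
  rate vanishes there, so descent is preserved); a `1e-12` tolerance
  absorbs floating-point rounding at the boundary.

## Activation

The network activation is the inverse hyperbolic tangent.  Two forms are
exposed: `exact_arctanh`, and the `taylor_cubic` truncation
`f(x) = x + x³/3` that fixed-point hardware realises with one multiplier
and one adder.  The cubic is the default for the classifier.  Both clamp
their output (and the exact form its input) into `[-1+eps, 1-eps]` with
`eps = 1e-6`, because the raw cubic exceeds 1 for `|x| > 0.82` while the
model's outputs must stay inside the open interval.  The truncation
error obeys `|arctanh(x) - (x + x³/3)| <= |x|^5 / (5(1-x²))` (geometric
tail of the odd series), which the tests check on a fine grid and which
bounds the float-vs-cubic discrepancy propagated through the network.

## Synthetic heart sounds

No patient recordings ship with the package; the generator in
`idpcg.synth` defines the study conditions:

* **Valve sounds** are Gaussian-modulated sinusoids: S1 60 Hz / 100 ms /
  amplitude 1.0, S2 90 Hz / 80 ms / 0.8, S3 and S4 40 Hz / 60 ms / 0.3
  in early and late diastole — standard auscultation ranges.  The
  annotated on/off edges sit at two Gaussian sigmas from the burst
  centre (sigma = dur/4), i.e. where the burst's Shannon envelope falls
  to roughly 10 % of its peak, so "annotated interval" and
  "envelope-visible interval" coincide by construction.
* **Cycle timing**: heart rate 70 bpm by default, systole 30 % of the
  cycle (diastole takes the remainder and absorbs the ±2 % per-cycle
  timing jitter), emulating the physiological shortening of diastole at
  higher rates and keeping systole < diastole across the 55–95 bpm
  sampling range.
* **Murmurs** are 100–400 Hz band-passed noise placed by clinical
  definition: aortic stenosis as a mid-systolic crescendo–decrescendo
  diamond (noise RMS 0.50 at the envelope peak — AS is loud), mitral
  regurgitation holosystolic and flat (0.35), mitral stenosis as a
  mid-diastolic rumble (0.40).
* **Noise**: white Gaussian noise scaled to a target SNR (default 20 dB,
  sampled 15–30 dB in datasets) against the clean transient+murmur
  power; records are peak-normalised to 0.95.
* Datasets are balanced over the five classes with per-record heart rate
  and SNR resampled, and every random draw derives from one master seed.

What the generator does **not** emulate: respiratory modulation and
splitting of S2, friction rubs and clicks, sensor artefacts, ectopic or
irregular rhythms, inter-patient spectral variability, and real murmur
time-frequency structure (turbulence is not stationary band-limited
noise).  Passing the end-to-end checks therefore demonstrates that the
pipeline's machinery is correct and self-consistent — not that the
reported operating points transfer to clinical recordings.

## Preprocessing and segmentation

* Zero-phase 4th-order Butterworth band-pass, 10–900 Hz, followed by db4
  wavelet denoising over 5 levels.  The soft universal threshold uses a
  noise scale estimated from the finest detail level only (VisuShrink);
  estimating a scale per level would shave in-band tones, and the tests
  pin the required behaviour (100 Hz tone attenuated < 5 %, 2 Hz drift
  by > 20 dB).
* The segmenter peak-picks a windowed Shannon-energy envelope
  (−s²·ln s², 15 ms window, 5 ms hop, 3-point smoothing) computed on a
  20–110 Hz band-limited copy of the signal: S1/S2 energy lives there
  while broadband murmur noise does not, so holosystolic or diastolic
  murmurs cannot corrupt peak picking.  The envelope normaliser is 1.2×
  the absolute peak, keeping the loudest burst below the turnover of the
  Shannon weighting so each transient has a single apex.
* Peaks closer than 200 ms are suppressed; peaks below 20 % of the
  envelope maximum are ignored.  Alternating peaks become S1/S2 by the
  rule that the systolic gap family is the shorter one.  Sound extents
  are the 10 % envelope crossings around each peak, bounded by midpoints
  to neighbouring peaks; the final cycle's diastole is closed at the
  running mean diastolic length (the next S1 is not observed).
  Degenerate cycles (systole ≥ diastole) are dropped with a warning.
* An *oracle* mode consumes ground-truth annotations so that features
  and classifier can be validated independently of segmentation quality.

## Features

F1/F2 are interval ratios averaged per cycle.  "Peak energy" in F3/F4 is
defined (the source material leaves it open) as the energy inside a
50 ms window centred on the in-interval Shannon-envelope maximum,
normalised by the full cycle energy.  F5/F6 Hann-window each systolic /
diastolic segment, zero-pad to ≤ 1 Hz resolution, average the magnitude
spectrum inside each of the 89 contiguous 10 Hz bins spanning
10–900 Hz, and average bins and cycles; segments are amplitude-normalised
per cycle first.  Consequently every feature, and the whole pipeline, is
invariant to global amplitude scaling.

## Classifier and training

6-12-5 feedforward network, inputs min/max-scaled to [-1, 1] (constant
features map to 0), targets coded ±0.9 one-hot (exact ±1 is unreachable
under output clamping).  Training is Levenberg–Marquardt on the
sum-of-squares error with an analytic Jacobian assembled from the
activation derivatives: damping ×10 on rejected steps, ×0.1 on accepted
ones (accepted-step MSE is therefore non-increasing by construction),
15 % validation split with early stop after 6 consecutive
non-improvements, at most 100 epochs.  Initial weights are uniform with
a 1/sqrt(fan-in) scale: the clamped cubic activation has zero derivative
once saturated, so initial pre-activations must stay inside the live
region `|z| < 0.82`.

Inference is a single static pass.  A "settle" mode
(`forward_settled`) is also provided that integrates the ID dynamics
per layer under constant drive until `|dx/dt| < 1e-6`; its fixed point
solves `g(x) = u` (i.e. `x = tanh(u)` for `K = 0`), which coincides with
the static pass only in the small-signal regime — the static reading is
the default.

## Fixed-point deployment

`FixedPointFormat` (default signed Q32.24) rounds weights, biases and
every arithmetic stage to the fixed-point grid with saturation,
mirroring hard-coded-weight inference.  On the trained classifier the
maximum score deviation from floating point is ~1e-6 and predicted
labels agree on >99.5 % of random inputs; both quantities are recomputed
by `scripts/acceptance.py`.

## Problem sizes

The end-to-end experiment trains on 200 records per class and evaluates
on a disjoint 200 per class (8 cycles per record at 2 kHz); the
segmentation audit uses 100 records at 20 dB SNR; Lyapunov checks run 20
random 4-neuron networks for 2000 RK4 steps at dt = 0.005.  These sizes
give stable statistics while keeping a full reproduction run around two
minutes on one CPU.

## Known limitations

* The simplified envelope segmenter assumes systole shorter than
  diastole and at least two clean envelope peaks; tachycardia beyond
  ~100 bpm with fixed sound durations, severe noise, or arrhythmia will
  degrade it.  It is a stand-in for full probabilistic (HSMM-based)
  segmentation, which is out of scope.
* Per-class operating points reported on synthetic data are surrogates;
  clinical performance claims require patient data the package does not
  have.
* The fixed-point emulation models rounding and saturation but not
  accumulator-width effects inside a multiply–accumulate chain.
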