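# Methods

## Overview

glucopipe is a software analogue of a dual-modality non-invasive glucose
monitor: optical (dual-wavelength PPG) plus electrical (bioimpedance
frequency sweep), fused with physiological covariates and regressed onto
blood glucose by a feed-forward network. Every stage is implemented and
tested in isolation; a seeded simulator supplies cohorts whose glucose
signatures are known by construction, so the pipeline's ability to
recover them is a measurable property rather than an assumption.

## Synthetic cohort

**Covariates.** Each participant draws age (integer, 18–25), height
(165 ± 20 cm), weight (65 ± 30 kg), heart rate (70 ± 28 bpm), blood flow
velocity (280 ± 100 mm/s), hemoglobin (160 ± 20 g/L), SpO₂ (94 ± 5 %),
and glucose (110 ± 15 mg/dL). The "±" is read as the *half-width of a
uniform distribution*, not a standard deviation: it guarantees every
draw stays inside the stated range, matching a range-style cohort table.
The default cohort size is 40; the default evaluation runs use 200 (see
"Problem sizes" below).

**PPG model.** Each channel is
`drift(t) + A_λ(g) · Σ_b pulse(t − t_b) + ε(t)` sampled at 100 Hz for
180 s (the sampling rate is a package choice; 100 Hz resolves PPG
morphology comfortably). Beats are spaced 60/HR s apart. The pulse is a
systolic Gaussian (σ = 0.09 s) plus a delayed dicrotic lobe (relative
amplitude 0.35, delay 0.25 s, σ = 0.12 s) — a morphological surrogate,
not a hemodynamic model, chosen so that baseline correction and peak
detection face realistic waveforms. Drift is a sum of 3 sinusoids with
random frequencies below 0.15 Hz and random phases (a motion/respiration
surrogate, amplitude 0.3 a.u.); ε is i.i.d. Gaussian (σ = 0.01 a.u.).
The glucose coupling is Beer–Lambert-inspired amplitude attenuation
`A_λ(g) = base_λ · exp(−ε_λ · g/110)` with ε_red = 0.35,
ε_ir = 0.25 — distinct per wavelength, and strictly decreasing in g.
Across the cohort's glucose range this moves pulse amplitude by roughly
±5–10%, well above the default noise floor; the magnitude is an explicit
surrogate exposed in `AcquisitionConfig`.

**Impedance model.** Single-dispersion Cole:
`Z(f) = R∞ + (R0(g) − R∞)/(1 + (i f/f_c)^α)` with R0_base = 500 Ω,
R∞ = 100 Ω, f_c = 70 kHz, α = 0.85, evaluated at 50–100 kHz in 5 kHz
steps. Glucose enters through `R0(g) = R0_base (1 − β (g−110)/110)`,
β = 0.2 — resistance falls as glucose rises, consistent with the
conductivity increase reported for glucose solutions. Gaussian noise
(σ = 0.5 Ω) is added to the real and imaginary parts; phase and
magnitude are recomputed from the noisy parts so the
magnitude² = real² + imag² invariant holds for every emitted sweep.
Three sweeps per participant (one per recorded minute).

**Determinism.** A master `SeedSequence` spawns one child stream per
participant; regeneration from the same seed is bit-identical, and
extending the cohort leaves earlier participants unchanged.

## PPG processing

Savitzky–Golay filtering with a 2 s window and order 3 estimates the
baseline; the corrected signal is the residual. With a window spanning
at least one full cardiac cycle the polynomial tracks drift rather than
pulses, which is the behaviour wanted here (a baseline estimator, not a
denoiser). Edge handling defaults to per-edge polynomial fits
(scipy's `interp`), which reproduces any signal of degree ≤ order
exactly — including at the boundaries — and keeps the filter's
polynomial-pass-through property testable to 1e-9; mirror padding is
available via `FilterConfig` but bends polynomial trends at the edges.

Peaks are strict local maxima kept greedily by descending prominence
subject to a 0.333 s refractory distance (180 bpm cap) and a prominence
floor of 0.5 × SD of the corrected signal. The detection algorithm is
deliberately simple plumbing; its parameters are config-exposed.

Statistics use population (divide-by-n) central moments with excess
kurtosis, and skewness = kurtosis = 0 by convention when the variance is
zero (degenerate fixtures stay usable). Entropy is Shannon entropy in
bits of an equal-width 8-bin histogram over [min, max]; with all values
equal the mass sits in one bin and H = 0. These conventions are frozen
and documented because the regressor only needs consistency — a
different but consistent convention would train equally well.

The 12-feature order interleaves channels: IR mean, Red mean,
IR variance, Red variance, …, IR entropy, Red entropy.

## Impedance PCA

Per participant, sweeps are averaged in the complex plane (real and
imaginary element-wise; phase and magnitude recomputed from the
averages) and flattened to 44 features (per frequency ascending: real,
imaginary, phase, magnitude). PCA is implemented directly: z-score each
column with the population SD (a zero-variance column gets SD 1 plus a
warning), form the covariance of the standardized data (= correlation
matrix, trace = 44), eigendecompose, sort eigenpairs by non-increasing
eigenvalue, keep the top k = 11, and fix each eigenvector's sign so its
largest-magnitude loading is positive (reproducible across linear-algebra
backends). Scores are `z-scored rows · Vᵀ`. Inside the pipeline the PCA
is fitted on training participants only; fitting on all rows is available
via `pca_fit_on="all"` for comparison with protocols that did not hold
data out.

## Network and training

Architecture 30 → 250 → 300 → 1: tanh hidden layers (tanh is the
activation the surrounding glucose-ANN literature uses; switchable to
identity, which makes the network exactly linear — a useful test hook),
linear output. Glorot-uniform initialization, zero biases, deterministic
per seed. Loss is mean squared error over samples; gradients are exact
chain-rule backpropagation, validated against a central finite-difference
oracle in the tests.

Training is plain full-batch gradient descent — with tens to a couple
hundred training rows, batching adds nothing. The learning rate starts
at 0.01 and is multiplied by 0.95 every 10 epochs (the decay factor is a
package default, config-exposed); at most 550 epochs ("iterations" are
read as full passes). Early stopping keeps the parameters of the best
validation epoch and halts after 50 epochs without improvement.

Inputs and target are standardized with statistics fitted on the
training rows only. The pipeline splits participants 80/20 into
train/test, then carves a further 20% of the *training* rows into an
internal validation set for early stopping — the held-out test rows are
touched only by the final evaluation, so the reported metrics are free
of early-stopping leakage. This is stricter than protocols that validate
on the same participants they report on; the difference is deliberate
and documented here rather than hidden.

## Evaluation

MSE, RMSE = √MSE, MAE, MARD = mean(|ŷ − y|/y) × 100%, and
R² = 1 − SS_res/SS_tot about the reference mean (NaN with a warning when
the references have zero variance). The Clarke error grid uses the
canonical 1987 inequalities, evaluated in the fixed order A, E, C, D,
else B; the order resolves boundary ties deterministically (A wins its
own boundary, then E, C, D). The five regions partition the plane —
verified exhaustively on a 5 mg/dL lattice over [20, 400]² against an
independently written vectorized oracle. The grid plot reproduces the
standard layout with region boundaries and labels.

## Problem sizes and runtime

Default end-to-end evaluation uses n = 200 participants rather than the
40 of the emulated acquisition protocol: 32 training rows cannot stably
constrain an 83,351-parameter network, so 200 (160 train / 40 test) is
the package's default for meaningful recovery measurement, while n = 40
remains one flag away. A full n = 200 run (simulation through
evaluation) completes in well under a minute on one CPU core.

## What passing tests do and do not show

The simulator's glucose couplings are smooth, monotone, and
participant-independent; real optical and dielectric glucose signatures
are weaker, confounded (temperature, perfusion, skin tone, contact
pressure), and drift within a session. Recovery of the synthetic signal
therefore demonstrates that the *pipeline* is correct and
information-preserving — baseline correction does not destroy amplitude
information, PCA retains the glucose axis, the trainer converges — not
that the sensing principle achieves any particular clinical accuracy.
The headline metrics this package prints are properties of its own
synthetic conditions and should never be quoted as clinical performance.

## Known limitations

- No first-principles optics or hemodynamics; no SpO₂ computation from
  the two wavelengths; no beat-morphology features (pulse width, notch
  timing).
- Peak statistics are computed on peak amplitudes only, not whole
  waveforms.
- No Cole-parameter fitting to measured sweeps; the Cole model is used
  generatively only.
- Plain gradient descent without momentum or adaptive steps; no
  hyperparameter search.
- The Clarke grid is the only clinical-consequence grid implemented
  (no Parkes/consensus or surveillance error grid).
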