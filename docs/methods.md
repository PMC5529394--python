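# Methods

## Scope and design

`reachdecode` is an analysis package: its end product is the set of numbered
drivers under `analysis/` (simulate → classify → reconstruct → motion
control), each a thin narrative over library code in `src/reachdecode/` that
is unit- and property-tested. No recordings for this paradigm are publicly
available, so the synthetic-data generator is a first-class component whose
defaults *are* the emulated session conditions; nothing downstream
knows whether its input came from the generator or from a real
NIfTI + events + motion triplet ingested through `reachdecode.io`.

## Experimental design emulated

A center-out reaching session: 6 runs, each with 40 reaching trials (five
repetitions of eight target directions 0°, 45°, …, 315°, order randomized
per run) and 5 rest trials interleaved strictly between reaching trials with
no two adjacent. Trials last 12 s; TR is 1 s. Each run carries a 24 s
lead-in, giving 24 + 45 × 12 = 564 s per run; the lead-in is the one free
parameter in the session timing and reconciles the stated run length of
9 min 24 s with 45 × 12 s of trials — session timing is otherwise
underdetermined, and the lead-in is configurable.

## Generative model of the data

**Tuning.** A fraction (default 0.5) of voxels is directionally tuned. Each
tuned voxel gets a uniform-random preferred direction; its k = 6 channel
weights are the nonnegative projections of a von-Mises-shaped tuning curve
(concentration κ = 2, a broad tuning typical of motor cortex) onto the
channel basis, rescaled so the voxel's peak response over direction equals
its amplitude (1.0 jittered uniformly by ±50%). This embodies the linearity
assumption the encoding model itself rests on — a voxel's response is the
summed activity of its neurons — while a `sparse` weight model (one or two
random channels per voxel) is available to break the smoothness assumption.
Untuned voxels have all-zero weights.

**Noise.** Trial-level responses are S·w plus i.i.d. Gaussian noise per
trial and voxel. The default `noise_sd = 1.45` was calibrated once so that
single-trial leave-one-run-out reconstruction lands at ≈ 50° mean absolute
error (50.3° over 8 calibration seeds), the error regime the method operates
in on real data; it was frozen before the acceptance checks were written and
is not a tuning knob. Temporal autocorrelation is deliberately absent at the
trial level; the time-series generator instead adds structured slow signals
(below).

**Time series.** Each reaching trial contributes a boxcar of its trial
response, delayed by the hemodynamic delay (default 4 s — the midpoint of
the 3–5 s range the BOLD response lags by; no HRF convolution beyond this
delay-plus-boxcar). On top: a per-voxel baseline offset (~100, emulating raw
scanner intensity), optional linear plus 0.005 Hz sinusoidal drift,
motion-coupled signal, and per-volume Gaussian noise. Head motion is a
demeaned random walk in six rigid-body parameters (translations mm,
rotations rad, scaled 50:1) plus a bump during each trial's 2 s movement
epoch whose translation/rotation mix depends on the reach direction — the
mechanism by which task-locked motion can masquerade as tuning. A ground
truth's `motion_coupling` (n × 6) injects `motion @ couplingᵀ` into the
signal.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: spatial voxel geometry and smoothness,
physiological noise spectra (cardiac/respiratory), HRF shape variability,
nonlinear BOLD saturation, between-run tuning drift, and realistic SMLR
behaviour under correlated voxel noise. Results here validate the
*machinery*, not empirical effect sizes.

## Preprocessing

Fixed per-run order: linear detrend → high-pass → motion regression →
baseline normalization → trial averaging. Processing runs jointly is
incorrect under per-run drifts and is explicitly tested against. Choices:

- **High-pass (0.01 Hz)** is discrete-cosine-basis nuisance regression (all
  cosines below the cutoff, plus the constant), the standard fMRI drift
  model, rather than an IIR filter: it is exactly linear, edge-stable, and
  matches how the cutoff is used in practice.
- **Baseline** is each voxel's mean over the rest-trial (center-hold)
  windows of that run, shifted by the same hemodynamic delay as reaching
  trials. "Baseline" is otherwise underdefined; the rest-period reading
  makes rest trials serve their natural purpose.
- **Hemodynamic shift** defaults to 4 s and is configurable; the averaging
  window is the trial duration minus the shift, capped at the trial end.
- **Low-intensity voxel removal** drops voxels whose mean raw intensity is
  below 0.1 × the grand-mean intensity (no principled value exists for the
  threshold; 0.1 only removes near-dead voxels).

A note on exactness: on noise-, drift- and motion-free input, baseline
normalization plus trial averaging reproduces the trial-level responses to
1e-6 (tested). Detrending and high-pass are *not* part of that identity —
the task boxcar itself has nonzero projection onto a line and onto slow
cosines whenever the randomized direction sequence is not perfectly balanced
in time, so the full pipeline recovers the signal only up to a small bias
(tested at correlation > 0.85 under strong drift). This is a property of the
preprocessing model, not an implementation artifact.

## Voxel selection

Sparse multinomial logistic selection counts: the classifier is fitted to 10
bootstrap resamples of the training trials; a voxel's SC value is the number
of resamples in which it receives any nonzero weight, and voxels with SC = 0
are removed. The sparse classifier is L1-penalized one-vs-rest logistic
regression (liblinear) on standardized responses at a fixed inverse penalty
C = 1. A cross-validated penalty path per resample would be the fuller
treatment, but it multiplies cost by roughly the grid size times the fold
count while leaving the selection behaviour that matters here — tuned voxels
retained, null data selecting at chance, SC monotone in signal amplitude —
unchanged; the fixed-C variant is therefore the default and the properties
are what the tests pin down. If selection retains nothing (e.g. all-zero
input), the pipeline warns and falls back to all voxels rather than dying.
Selection only ever sees training-fold trials; leakage is tested by
construction (a voxel informative only in the held-out run can never be
retained for that fold).

## Encoding model numerics

- **Channel phase**: centers at {0°, 60°, …, 300°}. The spacing is fixed by
  k = 6 over the circle; the phase relative to the 0° target is not
  determined by anything observable here and is configurable (`phase_deg`).
  The rectification exponent is likewise configurable (`power`, default 1 —
  plain half-wave rectification).
- **λ selection**: bootstrap-averaged BIC, `m·ln(RSS/m) + df(λ)·ln(m)` with
  df(λ) the trace of the ridge hat matrix, RSS summed over voxels, 50
  resamples, grid 10⁻³…10³ (13 log-spaced points). Ties take the smaller λ.
  Computed via one SVD per resample.
- **Inversion stabilizer**: ŵŵᵀ can be near-singular (duplicate or
  collinear voxels); ε defaults to 1e-6 × mean diagonal of ŵŵᵀ, i.e. a
  relative, scale-free ridge. ε = 0 demands exact invertibility and raises
  otherwise.
- **Read-out ties**: among candidate angles whose correlation is within
  1e-9 (relative) of the maximum, the smallest angle wins — deterministic
  and grid-order-independent. A constant estimated profile cannot be
  correlated; it falls back to nearest-Euclidean matching with a warning.
- **Classification candidates** are the idealized channel profiles of the
  eight trained directions, not empirical training means: the model's
  read-out should not depend on training noise, and the noise-free
  identifiability tests pin this choice down.

## Cross-validation and decoders

Leave-one-run-out (6 folds: 200 train / 40 test trials) for classification;
leave-one-direction-out (8 folds: 210 train / 30 test) for reconstruction of
directions never used in fitting. The MVPA baseline is a linear SVM with
C = 1 and one-vs-one multiclass handling (the LIBSVM default). The combined
decoder trains the same SVM on the encoding model's estimated channel
responses (a k = 6 feature space) instead of voxel space. Per-fold
accuracies are reported individually plus their mean. All randomness derives
from one master seed via fixed per-stage offsets, so results are
bit-reproducible and stages can be re-run independently.

## Evaluation statistics

Angles are degrees at every interface, radians internally. Angular variance
is 1 − ‖r‖ with r the mean resultant vector; a vanishing resultant flags
the mean direction as undefined (NaN) rather than inventing one. The
circular correlation is the Jammalamadaka–SenGupta form with the square root
in the denominator; it is validated against an independent implementation to
1e-10. A caution encoded in the analysis scripts: ρ computed on samples
*combined across all eight targets* is unstable, because the combined
marginal is near-uniform and its circular mean (the anchor of the sine
deviations) is then arbitrary — two nearly identical samples can produce a
large negative ρ. Per-target-direction ρ (each sample concentrated near its
target) is the stable quantity and is what the analysis reports.

## Problem sizes

The shipped analyses and tests use 80–100-voxel ROIs, 5–50 simulated
sessions per question, 10 selection bootstraps and 50 BIC bootstraps —
enough for every reported contrast to be far from its decision boundary
while a full run of the suite plus analyses stays in the minutes range on a
single core. All sizes are parameters, not constants.

## Known limitations

- The trial-level and volume-level noise routes share one `noise_sd`; the
  volume route yields higher effective SNR after within-trial averaging.
  They model different acquisition abstractions and are not calibrated to
  each other.
- SMLR here is the L1 realization, not the ARD-Bayesian original; SC values
  depend on the bootstrap definition chosen (10 resamples of training
  trials), for which no canonical definition exists.
- No spatial structure: voxel selection and SVM results do not speak to
  searchlight or spatially regularized variants.
- Reconstruction sits on a discrete grid (default 1°); sub-grid-step claims
  are meaningless by construction.
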