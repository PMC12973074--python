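# Methods

## Problem

Scalp EEG is cheap and mobile but blind to deep brain structures; fMRI sees
the ventral striatum (VS) but is expensive and immobile. This package
implements a group-level signal-to-signal translation: an interpretable
convolutional autoencoder maps a multichannel EEG window X (channels × L)
to the concurrently acquired, hemodynamically delayed VS BOLD window y
(length L), trained on aligned window pairs drawn from task runs of a
two-choice gambling paradigm. A regularized linear band-power model trained
on the identical folds provides the reference the deep model must beat, and
a statistical battery (surrogate null, regional specificity, native-rate
control, reward-modulation GLM) establishes that a decoded series means
what it claims to mean.

Everything runs against a seeded synthetic simultaneous EEG–fMRI generator
with known ground truth, so the full pipeline is testable on one CPU with
no data downloads.

## Synthetic session generator

One session is `n_runs` runs of a gambling task. Per run:

- **Events.** `trials_per_run` trials at a fixed 10 s spacing; feedback
  onset is 5 s into each trial (2 s fixation + 1 s choice + 2 s highlight
  delay) and lasts 2 s. Outcomes are a seeded permutation of exactly 50%
  win / 50% loss — exact balance rather than Bernoulli draws, which keeps
  the win/loss regressors orthogonal to the intercept and stabilises the
  functional-validity test at small trial counts.
- **EEG source.** Each planted source is band-limited Gaussian noise
  (4th-order Butterworth, zero-phase) with unit variance, multiplied by an
  amplitude gain: baseline `baseline_amp` (default 3), ×`win_gain`
  (default 2.0) for the 2 s after win feedback, ×`loss_gain` (default 1.2)
  after loss feedback. The source projects to the scalp through a fixed
  unit-norm spatial pattern (a smooth bump over the channel axis).
  Background is 1/f-power noise (slope 1, SD 1.0 per channel) plus white
  sensor noise (SD 0.5) — a conventional stand-in for the aperiodic EEG
  background. The default source amplitude is calibrated so the planted
  coupling is *strong on the EEG side*: its band-limited power clearly
  exceeds the background in its band. This keeps the study design
  coherent: the BOLD-side noise (the ~0.71 ceiling below), not envelope
  estimability from EEG, is the binding noise source, and the
  interpretability read-out has a recoverable target.
- **Target BOLD.** The source envelope (instantaneous amplitude × gain) is
  raised to `coupling_exponent` (default 2, i.e. band power — a mild
  nonlinearity that gives a nonlinear decoder measurable headroom over a
  linear one), z-scored, convolved with the canonical double-gamma HRF,
  delayed by the 6 s transport term, sampled every TR = 2 s, corrupted with
  Gaussian noise and z-scored. With `bold_noise_sd = 1` against the
  unit-variance drive the noise ceiling is r = 1/√2 ≈ 0.71 — the oracle
  `oracle_envelope_r` recomputes this ceiling per run from the stored truth.
- **Control ROIs.** "VC", "PMC" and "STN" receive `control_coupling`
  (default 0.3) times the target drive plus independent unit noise: weakly
  coupled by construction, so regional specificity is a falsifiable claim.

The canonical HRF is the difference of two gamma densities (shapes 6 and
16, unit dispersions, peak:undershoot 6:1, 32 s support, unit peak); its
mode sits at 5 s. Note the generator's timing convention: the BOLD carries
the HRF's own ~5 s response lag *plus* the 6 s transport delay. The
standard alignment removes only the transport term, so a residual
HRF-shaped lag remains in the aligned pairs — see "Known limitations".

## Preprocessing and alignment

Both modalities are z-scored per run (constant channels map to zeros). EEG
above the common rate is polyphase-decimated; BOLD is cubic-spline
interpolated to the common 100 Hz (linear interpolation is a config
switch). The EEG is then advanced by `delay_s = 6` s: sample i of an
aligned pair holds EEG at t and BOLD at t + 6 s, with the uncovered ends
trimmed, never padded. Optional utilities provide a 0.5–45 Hz zero-phase
band-pass and common-average re-referencing for real recordings; the
generator's output needs neither. Training windows (default 160 s full
scale, 40 s desk scale) are drawn at uniformly random start indices,
overlap permitted, fresh draws every epoch.

## Model

The front end ("compact block") is 16 parallel branches (4 at desk scale),
each: a pointwise spatial convolution (one learnable weight per channel),
a depthwise temporal convolution (kernel 51), ReLU, and a second depthwise
kernel-51 convolution that smooths the rectified signal into a power-
envelope-like series. These layers carry no bias, preserving the "spatial
filter → band filter → power" reading that the interpretability module
relies on. A kernel-3 projection convolution merges the branches; a
three-block encoder (conv 128/k3, normalization, GeLU, dropout 0.3,
max-pool stride 8) and a mirrored decoder (channels reduced ×4, linear
upsampling ×8 per block) follow; a final linear upsampling restores the
exact input length and a 1×1 convolution emits the prediction.

Design points that were genuinely open:

- **Normalization.** Batch normalization by default, instance
  normalization as a switch. The desk profile uses instance norm: with
  few batches per epoch the batch-norm running statistics lag the weights,
  which distorts early-stopping validation losses. Caveat: with three
  stride-8 pools, windows shorter than 1 024 samples collapse to a
  length-1 bottleneck where instance normalization zeroes the signal;
  desk windows are 4 000 samples so this regime is never entered.
- **Filter-bank initialization.** The temporal band kernels start as
  log-spaced Gabor kernels (2 Hz to 0.4 × Nyquist) and the smoothing
  kernels as unit-sum Hann windows, all fully trainable. Starting from
  white-noise kernels, gradient descent at desk scale spends most of its
  budget discovering that the kernels should oscillate at all; starting
  from a filter bank puts the block in its intended regime from epoch 0.
- **Upsampling** is linear interpolation (not transposed convolution);
  pooling uses floor semantics and the final resize makes the
  length-preservation contract exact for any L ≥ 512.
- The **decoder channel reduction** (÷4) applies to all decoder blocks.

The network and its optimiser are implemented in `eeg2bold.nn`, a small
numpy toolkit (conv/pool/norm/activation layers with explicit reverse-mode
gradients, AdamW, single-cycle cosine schedule). Every layer's backward
pass is finite-difference checked in the test suite.

## Training

AdamW (lr 3e-5, weight decay 3e-4, batch 32 at full scale; lr 1e-3, batch
16 at desk scale) under a single cosine half-cycle (T_max 50 / 30), no
restarts. Each fold holds out one run for testing and reserves one further
run for validation; every epoch draws fresh random windows from the
training runs. Validation loss is the full-run loss of the stitched
validation-run prediction — one stable number per epoch rather than a
noisy handful of random windows. Early stopping fires when validation loss
has exceeded its running best while training loss was non-increasing for
`patience` consecutive epochs (15 full scale, 8 desk); the returned model
carries the best-validation-epoch weights. The loss is
0.9 × MSE + 0.1 × (−Pearson r), averaged over the windows of a batch;
zero-variance windows contribute r = 0. The desk profile additionally adds
white noise (SD 0.5) to the input windows during training — with only a
few hundred seconds of training data per fold the model otherwise
memorises run-specific EEG background instead of the shared coupling.

Full-run predictions tile the run with windows advancing by a quarter
window and average the overlaps, which smooths the coarse temporal grid
the pooled bottleneck imposes on any single window.

## Baseline

Per channel and canonical band (delta 1–4, theta 4–8, alpha 8–13, beta
13–30 Hz): band-pass, square, 1 s moving average, log, z-score. Ridge
regression maps the instantaneous feature vector to the aligned BOLD
sample; the penalty is selected from a log grid by 5-fold inner
cross-validated correlation on the training runs (the validation run joins
the training data here — ridge's inner CV replaces epoch-level early
stopping). The baseline consumes the identical `FoldSpec` objects and
aligned pairs as the deep model.

## Statistical validation

- **Performance**: Pearson r between stitched prediction and held-out
  target.
- **Significance**: phase-randomization surrogates of the target
  (amplitude spectrum preserved exactly; DC and Nyquist untouched);
  one-sided p on positive r with add-one correction,
  p = (1 + #{null ≥ observed}) / (1 + N), default N = 1 000 (200 at desk
  scale). The null is calibrated (uniform p under independence;
  KS-checked in the suite).
- **Native-rate control**: prediction averaged over TR-long bins and
  correlated with the 0.5 Hz target, guarding against interpolation-
  inflated correlations.
- **Functional validity**: OLS of the predicted series on [intercept,
  HRF-convolved win regressor, HRF-convolved loss regressor]; the win and
  loss betas are compared by a one-sided paired t-test across folds.
- **Specificity**: per control ROI, Pearson r with the prediction and the
  prediction's OLS beta with event regressors as nuisance — the ROI-level
  analogue of a whole-brain regression on the decoded series (the
  volumetric GLM is out of scope). Bonferroni-adjusted p across the three
  control ROIs is reported alongside.
- **Group tests**: paired t with df = n_folds − 1 throughout; identical
  inputs are flagged degenerate rather than returning NaN.

## Interpretability

Branch importance is ablation-based: zero one branch's compact-block
output and record the drop in held-out r (Δr). Spatial *filters* are not
interpretable as scalp topographies, so the reported spatial pattern is
the forward-model projection C_x·w (channel covariance of the evaluation
EEG applied to the filter weights), unit-normalized. The frequency profile
is the magnitude response of the branch's temporal kernel multiplied by
the amplitude spectrum of the spatially filtered signal, max-normalized,
with resolution bounded below by fs/kernel ≈ 2 Hz. Across folds, branches
are ranked per fold and averaged *by rank*, with each fold's pattern
flipped to the consensus orientation first (patterns are sign-ambiguous;
the average is invariant to flipping any single fold's sign).

## Desk-scale profile and problem sizes

The full-scale defaults mirror the emulated acquisition (62 channels,
4 × 530 volumes, 160 s windows, 16 branches, encoder 128). All shipped
analyses and tests run the *desk-scale profile*: 16 channels, 4 branches,
encoder 32, 6 runs × 200 s (a 20-minute session; 10 runs for the 10-fold
comparison), 18 trials per run, 40 s windows, 30 epochs — sizes chosen so
each study is a single-CPU computation while every code path of the
full-scale model is exercised. Runs are kept at 200 s because the
hemodynamic autocorrelation leaves roughly one effective sample per
2–4 s; much shorter held-out runs make the per-run correlation estimate
itself the dominant noise source.

## What the generator does and does not emulate

It emulates the acquisition geometry (channel count, rates, volumes,
trial structure), a stationary spatio-spectral source with reward-locked
gain modulation, an envelope-to-BOLD transfer with the conventional
hemodynamic delay, 1/f EEG background, and weakly coupled
control regions. It does **not** emulate MR gradient or ballistocardiac
artifacts, volume conduction from multiple correlated sources, non-
stationary source dynamics, head motion, inter-subject variability, or
vascular/physiological BOLD confounds. Passing tests therefore show that
the pipeline recovers a known planted coupling under realistic noise and
timing — not that comparable accuracy is reachable on real recordings.

## Known limitations

- **Residual hemodynamic lag.** The generator places the full HRF
  convolution *plus* a 6 s transport delay between envelope and BOLD,
  while the standard alignment removes only the transport term. The
  aligned pairs therefore still contain the HRF's ~5 s response lag, which
  the encoder–decoder must internalise through its pooled bottleneck.
  Diagnostics with oracle inputs show this is the binding constraint on
  desk-scale accuracy: even with the true envelope supplied directly as an
  input channel the trained stack plateaus near r ≈ 0.4–0.55 against the
  0.71 ceiling, and the held-out r of the EEG-trained model typically
  lands at 0.2–0.3 — above the instantaneous linear baseline, below a
  lag-aware oracle regression. Section "Recovery study" of the README
  reports the measured values.
- Bit-exact reproducibility holds for fixed seeds on a fixed
  BLAS/single-thread configuration; across BLAS builds results match to
  numerical tolerance only.
- The linear baseline is one sensible instantiation (band powers + ridge);
  the reference it stands in for is underspecified upstream, and stronger
  linear baselines (e.g., lagged features) exist by construction.
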