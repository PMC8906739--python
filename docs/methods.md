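# Methods

This note documents the models, estimators and numerical choices in
`reachpop`, and what the synthetic sessions do and do not emulate.

## Task and synthetic behavior

The simulated task mirrors a variable-amplitude joystick operant: up to
150 trial slots, amplitude thresholds changing across three blocks
(default 4.2 / 5.7 / 4.2 mm), a reward delivered 1 s after the threshold
crossing, and a 3-s inter-trial interval during which movements are never
rewarded. Blocks advance every 50 *rewards* (not reaches), and the
simulated subject's amplitude distribution tracks the current threshold,
so labeled and planted blocks coincide and block-wise mean amplitude is
low-high-low by construction of the task, not by fiat.

Per trial the generator draws:

* **amplitude** — lognormal with median `1.5 × current threshold` and
  log-SD 0.45, truncated by redraw to [3, 24] mm. The task literature
  reports a broad right-skewed distribution (session means ≈ 8 ± 4 mm SD,
  maxima ≈ 24 mm) without naming a distribution; a lognormal with these
  parameters reproduces the reported spread, keeps roughly 80% of reaches
  suprathreshold, and the 3-mm floor guarantees every reach exceeds the
  speed-detection threshold so kinematic recovery is exact. With
  `amp_sigma = 0` the amplitude collapses to the median (useful for
  forced-amplitude tests).
* **direction** — uniform on a contiguous arc, default (−π/2, π/2).
  Restricting direction to an arc ≤ π keeps the *linear* regression on
  direction well-posed without circular statistics, matching how the
  analyses treat direction as a plain scalar in radians.
* **trajectory** — a straight-line stroke at the drawn direction with a
  minimum-jerk position profile: 300-ms outward stroke, 50-ms hold at
  peak displacement, 300-ms return. The single-peaked bell velocity
  matches observed joystick strokes; the hold makes the planted peak
  present verbatim in the sampled trace, which is why detected amplitude
  equals planted amplitude to float precision. The trace is zero during
  ITIs and the trial slot is fixed (6 s at the default 3-s ITI) so
  sessions are deterministic in length.

## Spiking model

Units are inhomogeneous Poisson. The rate of unit *u* is

```
λ_u(t) = b_u + [g_amp,u · A + g_dir,u · cos(θ − φ_u)] · g(t − t_start)
             + m_u · h(t − t_reward),     clipped at 0,
```

with `g` a Gaussian bump peaking 250 ms after reach start (σ = 120 ms,
support 0–650 ms) and `h` a bump peaking 200 ms after reward (σ = 150 ms).
Both kernels are **peak-normalized to 1**, so gains are interpretable as
the peak rate increment in Hz: an amplitude gain of 2 Hz/mm and an 8-mm
reach add 16 Hz at the kernel peak. Default gain ranges (amplitude
1.5–3 Hz/mm, direction 6–12 Hz/rad, reward 5–15 Hz, baselines 2–10 Hz)
give movement modulations of roughly 10–30 Hz — ordinary for motor
cortex — and were chosen once so that single-unit tuning is detectable
in a 45–150-trial session without being trivial. Direction-tuned units
get preferred directions at the arc edges, making the cosine tuning
monotone across the arc (a linear regression then has a consistent
sign). Spike times are Poisson counts per 1-ms bin with uniform sub-bin
jitter — exactly an inhomogeneous Poisson process for the
piecewise-constant 1-kHz rate, and equivalent to thinning at that
resolution.

The tagging block is generated segment-wise (piecewise-constant rates,
Poisson counts per segment, uniform times): tagged units fire at
`b_u (1 − inhibition fraction)` from pulse onset + planted latency to
pulse end; defaults are 60 pulses of 1 s at 8-s intervals, inhibition
fractions 0.7–0.95 and latencies 5–20 ms on 25% of units.

What the generator does **not** emulate: refractoriness, bursting,
correlated (shared) variability, drift and unit loss, direction-dependent
trajectory curvature, sub-movement corrections, and licking/posture
confounds. Passing recovery tests therefore shows the estimators are
correct and well-calibrated under Poisson variability at realistic rates;
it does not establish robustness to non-Poisson structure in real data.

## Kinematics

Speed is computed by central differences of position and smoothed with a
10-ms boxcar before thresholding. A reach is a maximal run of samples
with speed ≥ 5 mm/s containing at least one sample ≥ 15 mm/s
(hysteresis: on 15, off 5 mm/s — the source task describes
speed-based detection without thresholds, so these are package defaults,
exposed in the config). The event start is the last sub-off sample
before the run; windows are half-open `[start, stop)`; windows separated
by under 200 ms are merged so the outward stroke, hold and return count
as one movement. Amplitude is the maximum radial displacement in the
window and direction the angle at that sample, in (−π, π] with −π mapped
to +π. Reward labeling is threshold-inclusive (amplitude ≥ threshold
rewards the trial).

## Preprocessing

Spikes are counted in half-open 1-ms bins (a spike exactly on an edge
belongs to the later bin); PETH displays use 50-ms rate bins z-scored
against the 2500-ms pre-reach baseline. Z-scoring has two paths —
trial-averaged (default: baseline mean exactly 0, SD exactly 1) and
per-trial with pooled baseline statistics — both idempotent. Units with
baseline SD below 1e-6 are flagged and floored rather than producing
infinities. Gaussian smoothing (decoder path: σ = 24 ms on 1-ms rates,
smoothing *before* z-scoring) uses a ±4σ-truncated, renormalized kernel
applied by circular FFT convolution: linearity and total-mass
conservation then hold exactly, and since sessions start and end silent
the wrap-around is negligible.

## Consensus decoder

Each batch decoder is `W = pinv(Fᵀ) K`, the minimum-norm least-squares
solution, with a relative singular-value cutoff of 1e-10 (rank handling
is unspecified in the source analysis; the pseudoinverse makes the
all-zero-data case well-defined, W = 0). Batches draw movements without
replacement within a batch, independently across batches, from the
permuted non-held-out pool (with replacement, logged, only if the pool
is smaller than a batch). No intercept is fitted: F is z-scored, so
predictions are modeled around the joystick origin. The pooled Pearson r
(x and y concatenated) is the headline performance figure; per-dimension
r values are also reported. The shuffle control rotates the
movement-to-prediction correspondence by a random whole-movement offset
(pairs truncated to common length), 100 shuffles — the control is named
but not constructed in the source, so this is a package choice that
preserves both marginals while destroying correspondence. Partial
contributions zero all weights outside the subset; by linearity the
subset and complement predictions sum exactly to the full prediction.

## AMP/DIR dimensions

Per-trial movement-window counts (0–350 ms after reach start, covering
the outward stroke and hold) are z-scored per unit across trials.
Consensus regression averages the per-unit simple least-squares slope
over 50 batches of permuted trials. Gram-Schmidt runs AMP-first by
default (configurable; swapping the order changes ω_d, which is
documented rather than hidden — the regression coefficients themselves
are order-free). The β vectors are not normalized per-unit before
orthogonalization; only the final dimensions are unit-norm. Quintiles
are equal-trial-count bins with stable-sort tie-breaking. Per-unit
tuning is the slope of the unit's weight-scaled z activity against the
quintile means, and the AMP-minus-DIR slope difference is the
class-separation statistic.

## Naive Bayes classifier

λ is floored at `1/(N_k · n_bins)` so no test count has zero likelihood
(the flooring rule is a package choice). Trial-level classification sums
the log-likelihood over time bins and units (the per-bin decision rule
is also available); priors come from training-fold frequencies. Folds
are stratified by class so every training fold contains every class;
each trial lands in exactly one test fold per iteration. Ties in the
posterior resolve to the smallest tertile label. Classification uses
50-ms bins in the 0–600 ms post-reach-start window (which bins enter is
unspecified in the source; the movement window is the natural choice
given the tuning model).

## PCA

Columns (units) are mean-centered before the SVD; each component's sign
is fixed so its largest-|weight| element is positive, making results
reproducible across seeds. Explained variance fractions are relative to
total centered variance. Single-trial sqrt counts are noisy, so
individual fractions are small (a few percent at 48 units); the
movement-locked signal still dominates PC1, whose trial-averaged
trajectory peaks inside the outward stroke.

## Optotagging

The per-pulse paired comparison uses the pulse-length epoch immediately
before each onset as baseline and a one-sided (reduction) t test.
"Sustained" suppression is operationalized as the z criterion met in
every consecutive 100-ms sub-window of the pulse, with baseline mean and
SD taken over the per-pulse 100-ms baseline sub-window counts; the
sub-window length is a package choice (the source does not define the
sustain window). Both magnitude boundaries are inclusive (≥ 60%,
≥ 0.3 z). Latency and duration use the laser-aligned 1-ms PETH smoothed
with a 5-ms Gaussian; the trough inside the pulse defines maximal
inhibition and the half-max level is the midpoint between baseline and
trough. At low baseline rates and few pulses the first-crossing latency
estimator is biased early by noise (first-passage effect) by up to
roughly one smoothing width; calibration simulations with adequate rates
(≥ 15 Hz, ≥ 200 pulses) recover planted 20-ms latencies to well within
5 ms. Units with zero baseline spikes are flagged untestable rather than
classified.

## Problem sizes and determinism

Default sessions are 150 trials × 48 units (the reduced test sessions
are 30–60 trials × 12–24 units); calibration simulations use 1000
planted-null tagging units and 20-seed repetitions for recovery
statistics. These sizes give stable Monte-Carlo estimates while keeping
a full pipeline run to a couple of minutes on one CPU. All randomness
flows from a single seed through `numpy.random.SeedSequence` substreams
(one per stage), so toggling one stage never shifts another's draws and
identically seeded runs produce byte-identical reports.

## Known limitations

* Direction is treated linearly; sessions whose direction arc exceeds π
  would need circular statistics, which are out of scope.
* The decoder is linear and acausal (symmetric smoothing); no online
  decoding.
* The false-positive calibration of the tagging criteria is
  simulation-based (planted-null units), not anatomical.
* File-based sessions carry no ground truth, so recovery-oriented report
  fields (sensitivity vs truth, class separation) are defined only for
  synthetic sessions.
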