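# Methods

This note documents the models implemented in `avtrack`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions that shape the results.

## Forward model and boosting estimator

The encoding model treats each channel's response as a linear
convolution of stimulus features with lag kernels (temporal response
functions, TRFs):

    y[t] = Σ_i Σ_τ h_i[τ] · x_i[t − τ],    τ ∈ [−100, 600] ms.

Features and response are z-scored before fitting; fitted kernels are
rescaled back to raw units (`h_raw = h_z · sd(y)/sd(x)`) so that
condition-dependent response gains remain visible in the kernels, while
prediction accuracies stay scale-invariant.

**Kernel basis.** Kernels are expanded in 50 ms Hamming windows.  The
windows overlap at half-window spacing (20 ms after rounding to the
10 ms sample grid; 34 windows per band over the default lag range, one
flush with the end of the range).  A non-overlapping tiling is available
(`spacing_ms = basis_ms`, 14 windows) but cannot represent smooth
kernels: the best achievable correlation with a smooth Gaussian-bump
kernel under the tiled basis is ≈ 0.71, versus > 0.99 with the
overlapping basis.  The overlap default is therefore a representational
necessity, not a tuning choice.

**Boosting.** Per channel, the coefficient vector starts at zero and the
single (band, window, sign) increment of size `step` (default 0.005 of
the z-scored response SD) that most reduces the training ℓ2 error is
applied repeatedly.  A step is only accepted if it strictly reduces
training error, so the training loss is monotone.  Early stopping
monitors the validation ℓ2 error and reverts to the validation optimum
after `patience` (default 10) consecutive non-improving steps.  Ties
between candidate steps are broken by the lowest column index, making
fits bit-reproducible.  The training gradient and validation prediction
are updated incrementally (via the precomputed Gram matrix), so the cost
per step is O(columns), and the Gram matrix is shared across channels.

**Cross-validation.** Folds are contiguous time blocks (avoids leakage
between autocorrelated neighbors), deterministic given `(n_samples,
n_folds)`.  With the default four folds, each partition serves once as
the test set, the following block as validation, the remaining two for
training.  The reported per-channel accuracy is the Fisher-z mean over
test folds of the Pearson correlation between predicted and observed
response; the reported kernel is the mean over folds.  Underdetermined
problems (fewer than 10 samples per basis window) are rejected.

**Stopping rule scope.** Stopping is global per channel, not per
feature: a zero feature can never be selected (its candidate step cannot
reduce error), so its kernel is exactly zero.

## Stimulus features

* **Spectrogram** — 256 gammatone filters (scipy's IIR design) with
  ERB-spaced centers between 20 and 5000 Hz; filter outputs are RMS
  energies in non-overlapping 10 ms frames (landing directly at 100 Hz);
  centers below 100 Hz are discarded; the rest are averaged (unweighted)
  into 8 log-spaced bands over [100, 5000] Hz, then compressed with
  exponent 0.6.  Band averaging precedes the compression; this order
  follows the processing sequence stated for the original stimuli.
* **Acoustic onsets** — per band, a delay layer of 10 delays from 3 to
  5 ms (fractional-sample delays via linear interpolation on the 10 ms
  grid), a saturating nonlinearity `s(u) = c·u/(1 + c·u)` with `c = 30`,
  and a derivative-of-Gaussian receptive field (SD 2 ms) across the
  delay axis, half-wave rectified.  The receptive-field weights sum to
  zero, so steady states map exactly to zero and only rising edges
  produce output.  The exact coupling of these three components is
  underdocumented in the literature this model follows; all three
  parameters are exposed.
* **Lip aperture** — polygon (shoelace) area of the lip contour per
  frame, or ellipse area `π·a·b/4` from the horizontal/vertical axes;
  self-intersecting contours are rejected.  The 25 Hz series is
  upsampled to 100 Hz by FFT-based interpolation, which preserves the
  mean and the power of band-limited content exactly.
* **FIR utility** — the Hamming-window design rule
  `order = ceil(3.3·fs/Δf)` rounded up to even, with windowed-sinc taps
  for zero-phase application.  It reproduces the orders 1320 (low-pass,
  2.5 Hz transition at 1 kHz) and 166 (high-pass, 2 Hz at 100 Hz) used
  in standard M/EEG preprocessing chains.

## fROIs and the unique contribution of lip movements

Functional ROIs take all channels at or above a percentile (default
90th) of a whole-brain accuracy map, computed with linear interpolation
and an inclusive (≥) threshold — an all-equal map selects every channel,
and raising the percentile can only shrink the set.  The defining map
defaults to the harder (multispeaker) condition, where both acoustic and
visual features are expected to engage their sources.  The audiovisual
fROI is the set union of the acoustic and lip fROIs.

The unique contribution of lip movements is the percentage change of the
combined (acoustic + lip) model's fROI-averaged accuracy over the
acoustic-only baseline.  Percentage change explodes near a zero
baseline, so baselines below a configurable floor (default r = 0.01) are
flagged unstable, and non-positive baselines are reported as undefined
(droppable or retainable by flag — the literature is silent on this
case).

The bimodality coefficient uses bias-corrected sample skewness g1 and
excess kurtosis g2: `BC = (g1² + 1)/(g2 + 3(n−1)²/((n−2)(n−3)))`.
Benchmarks: ≈ 1/3 for normal samples, ≈ 5/9 ≈ 0.5556 for uniform
samples (the conventional bimodality threshold), larger for separated
mixtures.

## Frequentist inference

TFCE enhances a dependent-sample t map with the discretized integral
`Σ_h e(h)^E · h^H · Δh` (defaults E = 0.5, H = 2 — the field-standard
exponents — and step Δh = 0.1), with cluster extents `e(h)` taken on an
adjacency graph: nearest neighbors for time axes, a distance threshold
(default 1.5× grid spacing) for channel coordinates.  Positive and
negative parts are enhanced separately and recombined.  The null is the
distribution of the maximum |TFCE| under within-subject sign flips of
the difference maps (seeded, logged); element-wise p values are the rank
of the observed |TFCE| in that null.  Significant elements are grouped
into graph clusters, each reported with its extreme t value and the
Cohen's d of the cluster-averaged differences.  Tests are two-sided.

Scalar paired comparisons apply a Shapiro–Wilk gate (α = 0.05): normal
differences get the dependent-sample t test with d = mean/sd of the
differences; otherwise the Wilcoxon signed-rank test (exact for small
samples) with the matched-pairs rank-biserial correlation
`r_C = (R⁺ − R⁻)/(R⁺ + R⁻)`.

## Bayesian multilevel model

`behavior ~ 1 + tracking + (1 | subject)` with Student-t observation
noise; both variables z-scored, so the slope b is standardized.  Priors
are weakly informative and chosen to be negligible at these sample
sizes: Normal(0, 5) on intercept and slope, half-Student-t(3, 2.5) on
both scales, Gamma(2, 0.1) on the t degrees of freedom (shifted above
1).  The subject intercepts are integrated out with 32-node
Gauss–Hermite quadrature, leaving a 5-parameter posterior sampled with
an affine-invariant ensemble sampler (emcee, 32 walkers,
differential-evolution moves; defaults 1500 warm-up + 4000 retained
sweeps).  The low-dimensional marginalized posterior is what makes the
ensemble sampler mix well here; conditional subject-intercept means are
recovered from the same quadrature for reporting.

Reported: posterior mean/median of b, the 89% equal-tailed credible
interval (the quantile convention, not HDI), and PP(b > 0) computed as
the empirical fraction of positive draws.  An effect is significant only
if 0 is outside the CI *and* PP < 5.5% or > 94.5%.  Convergence is
checked with split-R̂ < 1.01 and bulk ESS > 400 per parameter (walkers
treated as chains); failing fits are flagged unreliable rather than
silently reported.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes:

* an envelope surrogate from pulse trains with Gamma(shape 2) inter-pulse
  intervals at a 4.1 Hz mean syllable rate, amplitude-jittered and
  smoothed with a 50 ms Hann window; 8 spectrogram bands are the
  envelope under band-specific slow modulations;
* onsets derived from that surrogate with the same edge detector used
  for real stimuli;
* a lip-aperture series that leads the envelope by 120 ms (visual speech
  precedes audio) and is mixed with an *independent* syllable-rhythm
  process; the mixing weight is calibrated on the realized signals
  (after orthogonalizing the independent part) so the lag-zero
  envelope–lip correlation hits the requested value exactly.  The lead
  autocorrelation caps the correlation reachable through the shifted
  path; beyond that cap the instantaneous envelope is blended directly.
  The target correlation is a parameter (default 0.3) because the
  empirical value for natural audiovisual speech varies by stimulus;
* responses as feature-kernel convolutions with per-condition gains,
  two spatial gain blobs ("acoustic" and "visual" regions) on a 7 mm
  channel grid, per-subject log-normal gains, plus 1/f^α noise
  (frequency-domain synthesis, default α = 1) of scale `noise_sd`;
* behavior from a per-subject tracking metric: standardized score
  `b·z(tracking) + u_subject + e` with `u ~ N(0, τ²)` and Student-t
  noise scaled so the total variance is ≈ 1 (making b the standardized
  slope), then mapped to a percent comprehension scale (clipped to
  [0, 100]) and 1–5 ratings (difficulty reverse-coded).

Default true kernels peak at 70/180 ms (acoustic) and 160/290 ms (lip),
Gaussian bumps of SD 40 ms with support in [0, 400] ms; condition gains
damp acoustics (×0.6) and boost lip responses (÷0.6 → ×1.0) in the
multispeaker condition.  Everything is deterministic given the recorded
seed: identical seeds give bit-identical datasets, and with
`noise_sd = 0` responses equal the stored convolutions exactly.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: real speech spectro-temporal statistics
(formants, co-articulation, pauses), nonlinear or adaptive neural
responses, physiological artifacts, sensor-level mixing/source leakage,
non-stationarity across a session, and any anatomical realism beyond a
rectangular channel grid.  Benchmarks on this generator validate the
*estimators* (recovery, calibration, determinism), not claims about
brains.

## Problem sizes for the simulation studies

The bundled validation studies use desk-scale sizes chosen to keep the
statistical questions answerable: 60 s single-condition recordings for
kernel recovery (noise SDs 0, 2, 8 for the degradation curve); 200 null
simulations × 500 permutations (12 subjects × 12 elements) for the TFCE
family-wise error; 12 subjects × 50 s for the contribution-sign study,
with the noise scale set so single-subject accuracies land in the
realistic 0.05–0.2 range, a 75th-percentile fROI (appropriate for
4-channel maps), and a 0.05 baseline floor — above the sampling error of
r — so unstable percentage changes are excluded; and 100
replicates of 29 subjects × 2 conditions with 400 retained sweeps per
fit for the Bayesian coverage and null-significance studies.  Larger
sizes sharpen the same estimates but do not change the logic of any
check.

## Known limitations

* Boosting's greedy credit assignment cannot uniquely attribute variance
  among strongly collinear features (e.g. spectrogram vs. onsets derived
  from it); summed/band-averaged kernels and predictions are stable, but
  per-feature kernels under collinearity are not identifiable — the
  motivation for the contribution statistic's model-comparison design.
* The percentage-change contribution is unstable for near-zero baseline
  accuracies; the floor flag should be respected in small-n studies.
* The ensemble sampler's walkers are treated as chains for R̂/ESS; this
  is conservative in the marginalized 5-D space but would be
  anti-conservative if the posterior were multimodal.
* TFCE p values inherit the resolution 1/(n_perm + 1); the reduced
  n_perm used in the bundled null study bounds, but does not pinpoint,
  attained error rates.
* Bounded behavioral scales interact with the Student-t likelihood:
  clipping piles observations at the scale ends, which inflates the
  sampling variability of the standardized slope without widening the
  credible interval (the unbounded-score posterior is frequentist-
  calibrated to within ~1%).  Under heavily clipped scores the joint
  CI + PP decision rule therefore runs slightly hot — ~15% false
  alarms at the 89% level instead of the nominal ~11% — which matters
  when treating the Bayesian rule as a frequentist test.
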