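# Methods

This note documents the models, conventions and numerical choices behind
`proprio`, and what the synthetic-data generators do and do not emulate.

## Pantograph kinematics

The manipulandum is modelled as a planar five-bar linkage: motor hubs at
(0, 0) and (d, 0) in the manipulandum frame (origin at the center of the
left motor), proximal links of length lp, distal links of length ld
meeting at the endpoint. The published design does not print the link
dimensions, so they are configuration parameters (defaults d = 2 cm,
lp = 2 cm, ld = 3 cm). The forward map takes the **elbow-up** intersection
of the two distal-link circles; the inverse map uses the elbows-outward
working mode (left elbow at α + β, right at α − β, with β from the law of
cosines) and verifies its choice by a forward round trip. Several motor
angle pairs can reach the same endpoint, so angle-level round trips are
only guaranteed within this working mode; position-level round trips
(IK∘FK at the endpoint) are exact to < 1e−9 cm.

Trajectories are straight segments with a trapezoidal speed profile:
accelerate at `accel` (default 20 cm/s², a configuration value — only the
peak velocity is a task parameter) to the commanded peak velocity, cruise,
decelerate symmetrically; short movements degenerate to a triangular
profile peaking at √(distance·accel). Sampling is 1 kHz.

Landmark triangulation is the linear DLT (SVD null vector of the stacked
two-view constraints); no iterative refinement is applied, keeping the
result deterministic. Near-parallel viewing rays (within 1°) set a
conditioning flag rather than raising. Camera-to-manipulandum registration
is the Umeyama least-squares similarity transform with the sign of the
smallest singular-vector pair corrected so det(R) = +1 always holds —
a mirrored correspondence set yields the best proper rotation with a
large residual, never a reflection.

The humerus abduction/adduction angle is the azimuth of the
glenohumeral→elbow vector projected on the XZ plane, measured from the −Z
axis, positive toward +X (lateral = abduction), range (−180°, 180°]. A
humerus parallel to the Y axis has no defined azimuth and raises. The
workspace angle map interpolates linearly between lattice nodes (exact at
the nodes) and Δangle for a displacement is the interpolated difference
between the displaced point and the start.

## Two-photon trace processing

Motion shifts are the integer argmax of the circular cross-correlation
computed in the Fourier domain after cropping 10% of each border; both
images are mean-subtracted first. Ties are broken by the smallest
|dy| + |dx|, then lexicographically. No sub-pixel interpolation.

Δf/f0 from raw fluorescence uses a running 8th-percentile baseline over
60 s windows; precomputed Δf/f0 is accepted everywhere else.

Deconvolution assumes the calcium impulse response is a single exponential
with τ = 0.8 s, i.e. an AR(1) process c[t] = γ·c[t−1] + s[t] with
γ = exp(−dt/τ). The solver minimizes ½‖c − y‖² + λ·Σs[t] subject to
s[t] ≥ 0, by the exact pool-adjacent-violators algorithm (each sample
opens a pool; adjacent pools merge while the inter-pool constraint is
violated). This is the standard sparse non-negative formulation for fixed
kernels; it is deterministic and O(n). The penalty is λ = 2·σ̂ with σ̂
estimated from the median absolute deviation of the trace's first
differences (σ̂ = 1.4826·MAD/√2); with noise-free input and λ = 0 the
solver returns the generating spikes exactly, and reconvolving them
reproduces the trace to RMSE < 1e−6.

Spike-rate densities place each deconvolved amplitude in its nearest 1 kHz
bin and convolve with a unit-sum Gaussian kernel of σ = 0.1 s ("0.1 s
width" is read as σ; FWHM would be the other defensible reading), then
multiply by the 1 kHz rate. The output grid starts half a kernel before
the trace so the time integral equals the total spike count exactly.

The evoked response is max over the post window minus mean over the pre
window. At 30 Hz the windows are discretized as 46 samples from the onset
sample (t ∈ [0, 1.5] s inclusive) and 22 samples before it
(round(0.75·30) = 22). The statistic is invariant to adding a constant to
the whole series.

The randomization test applies **one uniform circular shift to the entire
onset set** per shuffle (1999 shuffles), preserving the number and spacing
of events; independent per-event placement is available behind a flag.
The response profile is precomputed at every sample on the circularly
extended trace, so each shuffle is a gather, and the observed statistic
equals the direct per-event computation wherever windows are in range.
The threshold is the `method="higher"` empirical 99th percentile of the
1999 null values (the 1980th order statistic); under exchangeability the
strict-exceedance rate is then exactly 20/2000 = 1%, whereas interpolated
percentiles would be slightly anticonservative. Because the statistic uses
a post-window max, shifts within one window length of zero reproduce the
observed value; the null therefore always contains a fraction ≈ (post
window)/(session length) of near-observed values, and the test has power
only when sessions are much longer than the analysis window (the task's
~600 s sessions give ≈ 0.4%). Perfectly periodic stimulus schedules break
the test for the same reason; the task's jittered holds avoid this.

## Directional tuning

Per-direction responses (means of per-trial evoked peaks) are circularly
re-centered so the empirically largest response sits mid-axis, then fit
with f(x) = b0·exp(−((x − b1)/b2)²) by bounded least squares
(b0 ≥ 0, b1 within ±180° of the center, b2 > 0); b1 is mapped back to
[0°, 360°). Wrap-around is handled entirely by the re-centering — the
model itself is not periodic. CIs are t-based from the linearized
covariance at the optimum (df = n − 3); bootstrap CIs are not implemented.
Selectivity requires the b0 and b2 95% CIs to exclude zero. On flat data
the optimizer drives b2 to arbitrarily large widths and the b0/b2
Jacobian columns collapse; such fits (b2 > 1e4 or condition number > 1e8)
are reported as non-converged with a "flat" diagnostic and are never
called selective. Note that the CI criterion tests for a nonzero,
width-resolvable response bump: a neuron responding strongly but equally
in all directions is rejected through the degeneracy guard, while an
untuned neuron with zero-mean responses is rejected because its b0 CI
covers zero.

The Rayleigh test uses z = n·R̄² with the standard small-sample p
approximation p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)); it is computed
in-package (≈10 lines) rather than through a circular-statistics
dependency.

Preferred spatial-position angles: a home-to-target movement with
preferred direction b1 occupies the sector at angle b1 seen from the home
position; a target-to-home movement with preferred direction b1 starts
from a target located at b1 + 180°. The per-neuron angular shift is the
circular difference (b1_return + 180°) − b1_forward in [0°, 360°) —
exactly 180° for pure direction tuning and 0° for pure position tuning.
Definitional choice: the "position" of a movement is its start point; the
mid-trajectory point would shift all angles equally and leave the 180°/0°
dichotomy unchanged.

Δ ratio = (x̄ − ȳ)/max(x̄, ȳ) over mean peak responses of two matched
movement sets; per-neuron significance by two-sided Welch t-test
(α = 0.01), population mean by one-sample t-test. Kinematic sensitivity is
a linear regression of per-trial peaks on amplitude (mm) or velocity
(cm/s); the % change per doubling is evaluated at the midpoint of the
tested range (the reference point is not dictated by the task; the
midpoint is symmetric and always interior).

## Wide-field processing

Interleaved blue (calcium-sensitive) and violet (calcium-insensitive)
frames are split and linearly interpolated onto a shared regular 20 Hz
grid. Per pixel, the violet series is regressed onto the blue series (OLS
with intercept over the whole trial-averaged series) and the scaled violet
fluctuation **around its mean** is subtracted:
corrected = blue − slope·(violet − ⟨violet⟩). Subtracting the full
slope·violet + intercept expression would leave a near-zero-mean residual
whose baseline mean is an unusable Δf/f0 divisor; subtracting only the
fluctuation is the same correction plus the blue DC level, which makes
the subsequent normalization well-posed. Δf/f0 divides by the mean over
the 1 s preceding stimulus onset, so the baseline-window mean of the
unsmoothed Δf/f0 is exactly zero per pixel by construction. Temporal
smoothing is Savitzky-Golay, order 2, 450 ms = 9 points at 20 Hz (exact on
quadratics); the smoothed and unsmoothed stacks are both kept. Pixels with
zero violet variance are masked to NaN and reported.

The activation map is the post-stimulus frame maximizing the spatial mean
(optionally within a mask; ties go to the earlier frame), normalized to
its own peak. Atlas registration is a least-squares 2D affine on five
landmark pairs (bregma, lambda, the two anterolateral parietal tips, the
median frontal-pole point); the atlas is an abstract coordinate frame
supplied by the landmark file — no atlas raster is bundled. Contours are
the 0.5 iso-level of the normalized map, restricted to the connected
super-threshold component containing the peak; other components are
suppressed without disturbing the sub-level values the interpolation
needs.

## Behavior

The bias controller keeps a FIFO window of the last 10 non-aborted trials;
bias = fraction correct on medial − fraction correct on lateral trials.
When one side is absent from the window its fraction is defined as 0, so
the bias is computable from the first trial (a carry-last-bias variant is
available). The double sigmoid for P(medial) is evaluated verbatim with
τ1 = −0.5 (negative, well-defined since S1 = 30 is even), τ2 = 0.5,
S1 = 30, S2 = 12, clamped to [0, 1]; P(−1) = 0 exactly. As printed, the
function sits at ≈1 for bias ≳ −0.4 and ≈0 for bias ≲ −0.6, i.e. it
counteracts a lateral-biased animal but pushes strongly toward medial
otherwise; whether a sign or τ value was misprinted cannot be decided
from the formula alone, so it is implemented as printed and this
asymmetry is simply documented.

Psychometric fits maximize the binomial likelihood of
P(right) = γ + (1 − γ − λ)·Φ((x − pse)/σ) over signed displacement
(medial negative), with bounds pse ∈ [−20, 20] mm, σ ∈ [0.01, 50] mm,
γ, λ ∈ [0, 0.5); two starts guard against local minima. 95% CIs are
profile-likelihood intervals (ΔNLL = 1.9207, bisection on each side with
re-optimization of the other parameters). Complete separation pins σ or
the asymptotes at a bound and is flagged. Simulated recovery at 500
trials/level covers the true parameters in ≥90% of replicates per
parameter (boundary-true parameters such as γ = 0 are covered through the
closed lower interval end).

Probe-trial statistics report % right answers per stimulus class per
session; anterior vs posterior is a paired two-sided t-test across
sessions (session-level units throughout). Inactivation Δ% correct is the
per-session difference from the control site, tested against zero per site
with Bonferroni correction across sites.

## Synthetic data: what is and is not emulated

The generators are **phenomenological**. Tuned-population traces are a
zero baseline plus per-movement kernels — phasic: difference of
exponentials (50 ms rise, 800 ms decay, matching the sensor timescale the
deconvolution assumes); tonic: a boxcar over the movement + hold period
convolved with the same decay; mixed: their sum at half tonic weight —
scaled by the neuron's Gaussian tuning at the executed movement direction,
plus white Gaussian noise. Trial onsets are written both in seconds and as
0-based sample indices (the seconds are snapped to the sample grid so the
two never drift apart). A body-petal gain multiplies the response of
movements whose end position is nearer a configurable body-origin point
than their start. Trace noise statistics and baseline drift of real
recordings are not modelled: noise is white and Gaussian with a free SD,
there are no shared-noise correlations between neurons, no neuropil, no
overlapping somata, and no CNMF footprint extraction. Passing tests
therefore validate the analysis logic, not robustness to every real-data
artifact.

Null traces are AR(1) with innovation SD `noise_sd` and coefficient
defaulting to exp(−dt/0.8 s) ≈ 0.959 at 30 Hz (calcium-like
autocorrelation; the null model's memory is not otherwise constrained by
the task). Event times are uniform conditional on a minimum spacing of
2.25 s (one full analysis window) and full-window margins, via the
standard gap construction.

Wide-field stacks put baseline·(1 + signal·map·s(t) + γ·h(t)) in blue
frames and baseline·(1 + h(t)) in violet frames, each sampled at its own
timestamp and with additive Gaussian noise; h(t) is a vasomotion-like sum
of four random sinusoids (0.08–0.4 Hz), s(t) an alpha function peaking
250 ms after onset, the map a Gaussian disk with ground-truth center, and
γ = 0.8 the blue-channel hemodynamic gain.

Stereo scenes fix the scapulothoracic and glenohumeral points in the
manipulandum frame, place the wrist a hand-length above the endpoint, and
take the elbow as the posterior-most point of the humerus/forearm sphere
intersection — a deterministic, reachable-checked pose whose humerus
azimuth varies smoothly over the workspace. The camera world is the frame
of camera 1; the stored manipulandum→world similarity (axis swap, scale
10, depth offset) is returned as ground truth.

Behavioral sessions draw the stimulus side from the live controller
(or 0.5), the answer from the latent psychometric observer, probes
(anterior/posterior, default 15%) from stored association probabilities
(anterior 0.65 right, posterior 0.35 — anterior generalizing toward
lateral), and aborts at a configurable rate; the logged table includes the
pre-trial bias and P(medial) so the controller can be replayed exactly.

## Default study conditions

Defaults mirror the task: 8 cardinal/ordinal directions, 7 mm amplitude
(task range 5–8 mm), 2 cm/s velocity (range 2–3 cm/s), ~30 Hz two-photon
sampling, 40 fps interleaved wide-field acquisition, 1–2 s random holds,
15% probe trials, displacement levels 1–4 mm. Free parameters with no
printed value (trace noise SD 0.05 Δf/f0, 3 s inter-trial interval, abort
rate 5%, linkage dimensions, trapezoid acceleration) are stated where they
are defined and are not claims about the recordings. Calibration
experiments use 2000 null neurons (600 s sessions, 40 events) for the
randomization-test false-positive rate and 150 tuned neurons
(8 directions × 10 trials × 2 phases, trial-peak noise 20% of the peak
rate, preferred directions von Mises at 247.5° with κ = 2) for the
angular-shift distribution — sizes chosen to estimate both statistics
well inside their tolerance on a single core.

## Known limitations

- The deconvolution penalty scale (λ = 2·σ̂) is a heuristic; amplitudes of
  closely spaced spikes on noisy traces are shrunk accordingly.
- The randomization test loses power for periodic stimulus schedules and
  short sessions (see above); it reports, it does not warn.
- The Gaussian tuning model has no baseline term, so a constant offset in
  responses biases b2 upward.
- The selectivity criterion flags any resolvable response bump; it is not
  a test of tuning depth.
- Atlas registration is affine-only and single-session; no nonlinear
  warping, no multi-session alignment.
- The psychometric profile intervals assume the binomial likelihood is
  correct; overdispersion across sessions is not modelled.
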