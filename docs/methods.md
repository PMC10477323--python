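# Methods

## Model

The pupil is treated as a linear time-invariant (LTI) system: the
diameter trace is the convolution of a neural input with a fixed
pupillary response function (IRF). Two consequences drive the design:

* **IRF identification.** A sudden decrease in continuous illuminance is
  assumed to inject a near-instantaneous neural input, so the pupil's
  step response to darkening identifies the system. The *derivative* of
  the mean darkening response is therefore the impulse response, and it
  is parameterized as a gamma pdf
  `h(t) = c (θ^k Γ(k))⁻¹ t^{k−1} e^{−t/θ}` with onset fixed at 0.
* **Input deconvolution.** Given the IRF, the event-locked
  oddball-minus-standard response `y(t)` over 4 s is modeled as
  `a·γ(t; t₀, k, θ) ∗ h(t)`, a four-parameter gamma input (onset offset
  t₀, shape k, scale θ, amplitude a). The parameters themselves carry no
  biophysical meaning; only two summaries are propagated to statistics:
  the temporal mean `k·θ + t₀` and the excess kurtosis `6/k`.

Darkening responses at different illuminance steps are made commensurate
through the steady-state law `d(E) = C + A·e^{B·E}` (peak-normalized
diameter vs. illuminance in lx; A = 32.56, B = −0.48 lx⁻¹, C = −1.03,
taken as fixed constants). Each baseline-corrected segment is divided by
`d(E_after) − d(E_before)`, which is positive for darkening; brightening
pairs are rejected. Pupil constriction is deliberately not modeled — LC
activity relates to dilation — so only darkening segments enter the IRF,
pooled over circle appearances and disappearances.

## Numerical choices

* **Derivative and trough.** The derivative uses central finite
  differences at the working rate. The zeroing point ("the trough after
  the maximum peak inside 1.5 s") is localized on a 150 ms
  boxcar-smoothed copy of the derivative, and a trough must be the
  strict minimum of its ±100 ms neighborhood. Rationale: the 4 Hz
  low-pass is first-order, so residual ripple above the cutoff survives
  differentiation and would otherwise produce spurious troughs; the raw
  derivative (not the smoothed copy) is what gets zeroed and fitted. If
  no such trough exists (monotone decay), zeroing falls on the global
  minimum after the peak — for a clean gamma tail this is the last
  sample, i.e. effectively no truncation. The same trough rule truncates
  the oddball difference response, where it removes contamination from
  responses to subsequent tones (the 2 s inter-stimulus interval is
  shorter than the pupil response).
* **IRF fit.** Three free parameters (log k, log θ, c), Nelder–Mead on
  the OLS objective, deterministic 3×3 grid of starting shapes
  {0.5, 2, 8} × scales {0.05, 0.2, 0.8} s; the solution is insensitive
  to the starting point for this fit, which the suite verifies.
* **Input fit.** The fit runs on a 100 Hz decimation of the cleaned
  1000 Hz grid (both kernel and response are band-limited to 4 Hz; the
  unit tests confirm sub-1% fidelity against 1000 Hz-generated data).
  The input density enters the discrete convolution as bin-integrated
  mass (exact gamma-CDF increments), which stays accurate for
  impulse-like inputs (k ≪ 1) whose density is near-singular at onset.
  The onset offset is constrained to [0, 0.5 s] by a logistic
  reparameterization; the mean constraint `k·θ + t₀ < 4 s` is an
  additive penalty, feasible candidates are screened at return, and the
  returned fit satisfies both constraints exactly. Random starts:
  t₀ ~ U(0, 0.5 s), log k ~ U(log 0.05, log 20),
  log θ ~ U(log 0.01 s, log 2 s), a ~ U(0.1×, 10×) of a moment-matched
  amplitude. Starts are drawn as one stream, so the best of n starts is
  monotone in n at fixed seed. Nelder–Mead tolerances are 1e−8 with at
  most 1500 iterations per start; the iteration cap (rather than a
  larger one) trades a negligible objective difference on converged
  basins for a several-fold runtime reduction of the 100–1000-start
  search. A fit-quality gate (R² < 0.5) flags subjects whose response
  the model cannot match; an all-zero difference response returns
  amplitude ≈ 0 flagged `no_response`. An empirical-kernel variant uses
  the zeroed derivative of the illuminance response directly (normalized
  to unit area) in place of the fitted gamma; a kernel with an early
  negative lobe (constriction) is accepted with a warning.
* **Low-pass filter.** Zero-phase first-order Butterworth (forward–
  backward), cutoff 4 Hz, with 1 s reflective padding; the 4 Hz pass in
  `mean_dilation_response` is an additional filter application on top of
  preprocessing, matching the stated processing order.
* **Single-case test.** The Bayesian single-case point estimates are
  computed analytically through the Crawford–Howell form
  `t = (x − m̄)/(s·√((n+1)/n))`, df = n − 1: the percent rank is the t
  CDF and the one-tailed p the corresponding tail (computed via the
  survival function to keep extreme p-values, ~1e−19 for the kurtosis
  comparison, free of `1 − CDF` cancellation). A Monte-Carlo posterior
  backend (`method="montecarlo"`) exists for cross-checking and agrees
  with the analytic rank within ±0.1 points at 10⁶ draws. Holm families
  contain exactly the two tests of one analysis block (mean time,
  kurtosis). The KS normality screen uses plug-in mean/SD and flags the
  Lilliefors caveat. One-tailed direction is inferred from the sign of
  (case − control mean) and reported.
* **Microsaccades.** LOWESS with a 25 ms span reduces, on a uniform
  grid with tricube weights, to a fixed convolution kernel in the
  interior (the local linear term vanishes by symmetry) with explicit
  weighted fits at the edges. Velocity comes from a ±2-sample moving
  window; thresholds are λ = 6 median-based SDs per component
  (elliptical criterion), minimum duration 6 ms — canonical values for
  the algorithm family, exposed in `DetectionParams`. Amplitude is the
  onset-to-offset displacement. Per-eye detections are merged by union
  within 10 ms (binocular AND available). Rates are per-trial sums of
  unit-area Gaussian kernels (σ = 50 ms, 2 ms grid; single-event peak
  (σ√2π)⁻¹ ≈ 7.98 Hz), baseline-corrected trial-wise over the last
  200 ms before onset. The inhibition minimum is searched in
  [0, 600 ms]; on a flat minimal plateau the plateau midpoint is used
  (a rectangular dip is thus measured at its centre); peak inhibition
  averages ±50 ms around it and the window mean runs from onset to the
  660 ms default rebound (re-estimable as the first zero crossing).

## Preprocessing

The validity pass mirrors the published defaults of the Kret &
Sjak-Shie algorithm: diameter range 1.5–9 mm, dilation-speed and
trendline-deviation gates at 16 MADs, 50 ms trimming at the edges of
gaps ≥ 75 ms, islands < 40 ms separated by > 40 ms removed. Two
absolute floors (speed 10 mm/s, deviation 0.1 mm) keep the MAD gates
meaningful on (near-)noise-free recordings, where the MAD collapses and
a pure multiplier would reject arbitrarily small fluctuations. The pass
is a pure function of the raw recording (values plus acquisition mask),
so it is stable under repetition.

The combined signal is the two-eye mean where both are valid and the
surviving eye otherwise. Filtering runs on a fully interpolated copy;
the 250 ms interpolation limit is then judged against the *acquisition*
gap (samples the tracker lost), not against spans enlarged by quality
trimming — a 200 ms blink remains interpolable after its edges are
trimmed, while a 300 ms one stays invalid. The off-fixation rule reads
4.74° as the exclusion circle's radius and is applied before
interpolation; peak normalization (per session, after exclusion) divides
by the session maximum of the cleaned signal.

## Synthetic data

The generator emulates the two study paradigms at 500 Hz with known
ground truth; its defaults are the study conditions, not tuning knobs:

* **Schedules.** Illuminance: 5 sessions × 24 trials (6 presentations of
  4 levels at 5.30/5.80/9.60/13.30 lx on a 7.30 lx background, 45 s
  rest, 5 s circle + 5 s gap), giving 24 darkening and 24 brightening
  changes per session. Oddball: 30 oddballs among 120 standards at a
  2 s ISI, positions uniform under a no-two-consecutive-oddballs
  constraint (sampled exactly via the stars-and-bars bijection; the
  constraint is a modeling choice exposed as `allow_adjacent`).
* **Pupil.** Baseline 2.82 mm (the control-sample baseline diameter),
  with 0.35 mm per peak-normalized unit linking the steady-state law to
  mm. Darkening/brightening transitions follow the cumulative IRF /
  constriction kernel, so the scaled segment derivative is exactly the
  IRF density; tone responses add the bin-integrated input convolved
  with the unit-area IRF. Default truths: IRF shape 2.5, scale 0.24 s
  (mean 600 ms); oddball input mean ≈ 657 ms, excess kurtosis ≈ 2.5,
  amplitude 0.12 mm; standard tones carry no input, so the difference
  response isolates the oddball input. The constriction shape
  (2.0, 0.15 s) is a plausible mirrored gamma — the analysis never
  models it. White noise SD 0.01 mm per eye on a shared signal,
  sinusoidal drift 0.03 mm at a 60 s period, blinks at 6/min lasting
  0.1–0.3 s with 0.8 mm edge spikes to exercise gap-edge trimming.
* **Gaze.** Ornstein–Uhlenbeck fixational drift (diffusion 0.06 °/√s,
  1 s time constant), microsaccades from a thinned Poisson process at
  1.2 Hz with 70% rate suppression in the 0–350 ms post-stimulus window,
  log-normal amplitudes (median 0.4°, log-SD 0.35), raised-cosine
  velocity profiles obeying a 100 s⁻¹ main-sequence slope, 25 ms dead
  time between events.

What the simulator does **not** capture: pupil-size foreshortening with
gaze angle, saccadic spike artifacts in the pupil channel, cognitive or
arousal drifts correlated with task events, non-stationary microsaccade
statistics, and tracker-specific noise spectra. Passing recovery tests
therefore demonstrates correctness of the inference chain under the
model's own assumptions, not robustness to every artifact of real
recordings.

## Problem sizes in the test suite

The multi-start deconvolution tests run with 100 random starts (the
analysis default is 1000) on the 100 Hz grid, and recovery studies use
20 seeds at the default noise level with 30 oddballs per seed; the IRF
noise study uses σ = 0.05 on the mean response. These sizes keep the
full suite in the tens of minutes on a single core while leaving the
statistical conclusions (bias < 10%, kurtosis ordering, ±10% mean-time
recovery) stable across seeds.

## Known limitations

* The gamma input parameters (k, θ, a) are not separately identifiable
  from a single response; only mean and kurtosis are interpreted.
* The amplitude multiplies a *normalized* gamma density; residual sums
  of squares are therefore not comparable with conventions that scale an
  unnormalized kernel, though the propagated summaries are invariant.
* Truncation at the post-peak trough removes late contamination but
  also discards genuine late response mass; recovered means are mildly
  biased toward zero (about −5% at default noise), well within the
  tolerances used.
* The group-level fallback IRF for subjects without an illuminance task
  must be supplied by the user; no default is shipped.
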