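# lcpupil

Inference of locus-coeruleus (LC) input from pupillometry.

Phasic activity of the locus coeruleus — the brainstem's noradrenergic
hub for attention — is indirectly visible in the pupil: under a linear
time-invariant (LTI) assumption, the pupil-diameter trace is the
convolution of a neural input with a pupillary response function. This
package implements that inference chain for auditory-oddball paradigms,
for researchers in pupillometry and computational psychophysiology:

1. **Preprocessing** (`lcpupil.preprocess`) — Kret & Sjak-Shie-style
   cleaning of binocular 500 Hz recordings: range and dilation-speed
   gates (MAD thresholds), gap-edge trimming, trendline-deviation and
   island rejection; eye averaging, 4 Hz zero-phase low-pass,
   upsampling to 1000 Hz, linear interpolation across gaps ≤ 250 ms,
   off-fixation exclusion (4.74° radius) and per-session peak
   normalization.
2. **Individual response function** (`lcpupil.irf`) — the IRF *h(t)* is
   estimated from responses to sudden illuminance decreases. Segments
   are rescaled through the steady-state law
   *d(E) = C + A·exp(B·E)* (A = 32.56, B = −0.48 lx⁻¹, C = −1.03),
   averaged, and the time derivative of the mean response (zeroed after
   the trough following its peak within 1.5 s) is fitted with a gamma
   pdf *c·(θᵏΓ(k))⁻¹ tᵏ⁻¹ e^(−t/θ)* by Nelder–Mead least squares.
3. **Neural input** (`lcpupil.neural_input`) — the oddball-minus-standard
   response over 4 s, truncated after its first post-peak trough, is
   fitted with *a·γ(t; t₀, k, θ) ∗ h(t)*, a four-parameter gamma input
   convolved with the IRF, using a 1000-start random search
   (t₀ ≤ 500 ms, input mean k·θ + t₀ < 4 s). Inputs are summarized by
   their **mean time** (k·θ + t₀) and **excess kurtosis** (6/k):
   impulse-like inputs have high kurtosis, sustained wave-like inputs
   low kurtosis.
4. **Single-case statistics** (`lcpupil.singlecase`) — Crawford–Garthwaite
   single-case comparison of one subject against a small control sample
   (analytic Crawford–Howell form, t = (x − m̄)/(s·√((n+1)/n))), with
   step-down Holm correction and KS normality screening.
5. **Microsaccades** (`lcpupil.microsaccades`) — LOWESS smoothing (25 ms
   span), Engbert–Kliegl velocity-threshold detection (amplitude
   0.08–1.5°, peak velocity 8–150°/s), Gaussian-kernel rate (σ = 50 ms,
   2 ms grid) and oddball-locked inhibition metrics.
6. **Synthetic data** (`lcpupil.synthetic`) — a forward simulator for
   both tasks (illuminance: 5 × 24 trials, 4 levels; oddball: 30/120
   tones, 2 s ISI) generating two-eye recordings with known ground
   truth: gamma-shaped dilations, exponential steady-state levels,
   blinks, drift, noise, fixational gaze and injected microsaccades
   with post-stimulus rate inhibition.

## Worked example

```python
import numpy as np
from lcpupil import (SimulationConfig, make_oddball_schedule, simulate_pupil,
                     clean_and_combine, normalize_session, extract_trials,
                     build_difference_response, fit_input,
                     crawford_test, ControlSummary)

cfg = SimulationConfig()                      # control-like subject
sched = make_oddball_schedule(seed=11)        # 30 oddballs, 120 standards
rec = simulate_pupil(sched, cfg, seed=11)

cleaned, report = clean_and_combine(rec.pupil_left, rec.pupil_right)
cleaned = normalize_session(cleaned)
diff = build_difference_response(
    extract_trials(cleaned, sched.oddball_times),
    extract_trials(cleaned, sched.standard_times))
fit = fit_input(diff, cfg.irf_truth, n_starts=100, seed=11)
print(f"input mean time {fit.mean*1000:.0f} ms "
      f"(truth {cfg.input_truth.mean*1000:.0f} ms), "
      f"excess kurtosis {fit.excess_kurtosis:.2f}")

res = crawford_test(fit.mean * 1000, ControlSummary(22, 657.0, 337.0))
print(f"percent rank {res.percent_rank:.2f}%, one-tailed p {res.p_one_tailed:.3f}")
```

prints

```
input mean time 621 ms (truth 657 ms), excess kurtosis 1.91
percent rank 45.85%, one-tailed p 0.459
```

— the deconvolved input's centre of mass lands within 10% of the
generating truth, and its mean time is unremarkable relative to the
control distribution (p ≫ 0.05), as expected for a control-like subject.

A command-line interface mirrors the library
(`lcpupil simulate | preprocess | fit-irf | fit-input | single-case |
microsaccades | run-all | reproduce-stats`).

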