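"""Microsaccade detection, rate estimation, and stimulus-locked inhibition.

Gaze is first smoothed with locally weighted linear (LOWESS-style)
regression over a 25 ms span.  Detection follows the velocity-threshold
algorithm of Engbert & Kliegl: velocity from a +/-2-sample moving window,
an elliptical threshold at ``lambda`` times a median-based velocity SD per
component, candidate events as supra-threshold runs of a minimum duration,
then amplitude (0.08-1.5 deg) and peak-velocity (8-150 deg/s) gates.

Rates are computed per trial by summing unit-area Gaussian kernels
(sigma = 50 ms) over event onsets on a 2 ms grid, baseline-corrected
trial-wise against the mean rate in the 200 ms before stimulus onset.
Inhibition metrics quantify the transient post-stimulus rate drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SampledSeries

__all__ = [
    "MicrosaccadeEvent",
    "RateSeries",
    "InhibitionMetrics",
    "DetectionParams",
    "smooth_gaze",
    "detect",
    "rate",
    "baseline_correct",
    "inhibition_metrics",
]


@dataclass(frozen=True)
class MicrosaccadeEvent:
    onset: float  # s
    offset: float  # s
    amplitude: float  # deg, onset-to-offset displacement
    peak_velocity: float  # deg/s
    eye: str = "both"


@dataclass
class RateSeries:
    """Smoothed microsaccade rate on a trial-time grid (2 ms step).

    ``trial_rates`` holds the per-trial rate matrix so that baseline
    correction can operate trial-wise before cross-trial averaging."""

    times: np.ndarray
    rate: np.ndarray
    trial_rates: np.ndarray
    baseline_corrected: bool = False


@dataclass(frozen=True)
class InhibitionMetrics:
    peak_inhibition_hz: float
    window_mean_inhibition_hz: float
    minimum_time_s: float
    rebound_time_s: float


@dataclass
class DetectionParams:
    """Velocity-threshold detection knobs.  ``lambda_threshold`` and the
    minimum duration are the canonical values of the algorithm family."""

    lambda_threshold: float = 6.0
    min_duration_ms: float = 6.0
    amplitude_range_deg: tuple[float, float] = (0.08, 1.5)
    peak_velocity_range: tuple[float, float] = (8.0, 150.0)
    merge_ms: float = 10.0
    binocular: str = "union"  # or "and"


def smooth_gaze(gaze: SampledSeries, span_ms: float = 25.0) -> SampledSeries:
    """Locally weighted linear smoothing (tricube weights) with the given
    temporal span; length preserved.

    On a uniform grid with a symmetric window the interior estimate
    reduces to a fixed convolution kernel; edge samples get explicit
    weighted linear fits over their asymmetric windows.
    """
    half = int(round(span_ms / 1000.0 * gaze.rate / 2.0))
    if 2 * half + 1 < 3:
        raise ValueError("span must cover at least 3 samples")
    x = gaze.values
    n = len(x)
    offs = np.arange(-half, half + 1)
    w = (1 - np.abs(offs / (half + 1)) ** 3) ** 3  # tricube
    kernel = w / w.sum()
    out = np.convolve(x, kernel[::-1], mode="same")
    # asymmetric edge windows: weighted local line fit evaluated in place
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        ti = np.arange(lo, hi) - i
        wi = (1 - np.abs(ti / (half + 1)) ** 3) ** 3
        W = np.sum(wi)
        tw = np.sum(wi * ti)
        ttw = np.sum(wi * ti * ti)
        yw = np.sum(wi * x[lo:hi])
        tyw = np.sum(wi * ti * x[lo:hi])
        det = W * ttw - tw * tw
        out[i] = (ttw * yw - tw * tyw) / det if det > 0 else yw / W
    return SampledSeries(out, gaze.rate, gaze.start, gaze.valid.copy())


def _velocity(x: np.ndarray, rate: float) -> np.ndarray:
    """+/-2-sample moving-window differentiation (deg/s)."""
    n = len(x)
    if n < 5:
        raise ValueError("series shorter than the velocity kernel")
    v = np.zeros(n)
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) * rate / 6.0
    return v


def _median_sd(v: np.ndarray) -> float:
    med = np.median(v)
    sd = np.sqrt(np.median(v**2) - med**2)
    return float(max(sd, 1e-12))


def detect(
    gaze_x: SampledSeries,
    gaze_y: SampledSeries,
    params: DetectionParams | None = None,
    eye: str = "both",
) -> list[MicrosaccadeEvent]:
    """Detect microsaccades in one eye's (smoothed) gaze trace."""
    params = params or DetectionParams()
    rate_hz = gaze_x.rate
    vx = _velocity(gaze_x.values, rate_hz)
    vy = _velocity(gaze_y.values, rate_hz)
    sx = _median_sd(vx)
    sy = _median_sd(vy)
    lam = params.lambda_threshold
    crit = (vx / (lam * sx)) ** 2 + (vy / (lam * sy)) ** 2 > 1.0

    min_len = max(int(round(params.min_duration_ms / 1000.0 * rate_hz)), 1)
    events = []
    n = len(crit)
    i = 0
    while i < n:
        if not crit[i]:
            i += 1
            continue
        j = i
        while j < n and crit[j]:
            j += 1
        if j - i >= min_len:
            speed = np.hypot(vx[i:j], vy[i:j])
            pv = float(np.max(speed))
            amp = float(
                np.hypot(
                    gaze_x.values[j - 1] - gaze_x.values[i],
                    gaze_y.values[j - 1] - gaze_y.values[i],
                )
            )
            a_lo, a_hi = params.amplitude_range_deg
            v_lo, v_hi = params.peak_velocity_range
            if a_lo <= amp <= a_hi and v_lo <= pv <= v_hi:
                events.append(
                    MicrosaccadeEvent(
                        onset=gaze_x.start + i / rate_hz,
                        offset=gaze_x.start + (j - 1) / rate_hz,
                        amplitude=amp,
                        peak_velocity=pv,
                        eye=eye,
                    )
                )
        i = j
    return events


def merge_binocular(
    left: list[MicrosaccadeEvent],
    right: list[MicrosaccadeEvent],
    params: DetectionParams | None = None,
) -> list[MicrosaccadeEvent]:
    """Combine per-eye detections: union with onset merging within
    ``merge_ms`` (default) or binocular intersection ("and")."""
    params = params or DetectionParams()
    tol = params.merge_ms / 1000.0
    if params.binocular == "and":
        kept = [
            ev for ev in left if any(abs(ev.onset - o.onset) <= tol for o in right)
        ]
        return sorted(kept, key=lambda e: e.onset)
    merged: list[MicrosaccadeEvent] = []
    for ev in sorted(left + right, key=lambda e: e.onset):
        if merged and ev.onset - merged[-1].onset <= tol:
            continue
        merged.append(ev)
    return merged


def rate(
    onsets,
    trial_onsets,
    t_min: float = -0.2,
    t_max: float = 1.0,
    sigma_ms: float = 50.0,
    step_ms: float = 2.0,
) -> RateSeries:
    """Smoothed rate: per trial, sum of unit-area Gaussian kernels centred
    on event onsets (relative to trial onset), averaged across trials.

    The kernel peak for a single event is ``1 / (sigma * sqrt(2 pi))``,
    about 7.98 Hz for sigma = 50 ms."""
    trial_onsets = np.asarray(list(trial_onsets), dtype=float)
    if trial_onsets.size == 0:
        raise ValueError("no trials supplied")
    onsets = np.asarray(list(onsets), dtype=float)
    sigma = sigma_ms / 1000.0
    grid = np.arange(t_min, t_max + 1e-12, step_ms / 1000.0)
    trial_rates = np.zeros((len(trial_onsets), len(grid)))
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    for i, t0 in enumerate(trial_onsets):
        rel = onsets - t0
        rel = rel[(rel > t_min - 5 * sigma) & (rel < t_max + 5 * sigma)]
        for r0 in rel:
            trial_rates[i] += norm * np.exp(-0.5 * ((grid - r0) / sigma) ** 2)
    return RateSeries(
        times=grid, rate=trial_rates.mean(axis=0), trial_rates=trial_rates
    )


def baseline_correct(rs: RateSeries, window_ms: float = 200.0) -> RateSeries:
    """Subtract, per trial, the mean rate over the last ``window_ms``
    before stimulus onset (t = 0), then re-average across trials."""
    sel = (rs.times >= -window_ms / 1000.0) & (rs.times < 0)
    if not sel.any():
        raise ValueError("rate grid does not cover the pre-stimulus window")
    baselines = rs.trial_rates[:, sel].mean(axis=1, keepdims=True)
    corrected = rs.trial_rates - baselines
    return RateSeries(
        times=rs.times.copy(),
        rate=corrected.mean(axis=0),
        trial_rates=corrected,
        baseline_corrected=True,
    )


def inhibition_metrics(
    diff_rate: RateSeries,
    search_window_s: float = 0.6,
    peak_half_width_s: float = 0.05,
    rebound_s: float | None = 0.66,
) -> InhibitionMetrics:
    """Quantify stimulus-locked inhibition on a baseline-corrected
    (oddball-minus-standard) rate.

    The minimum is located within the first 600 ms (the midpoint of a flat
    minimal plateau is used, so a rectangular dip is measured at its
    centre); peak inhibition is the mean over +/-50 ms around it;
    window-mean inhibition is the mean from stimulus onset to the rebound
    time (default 660 ms; pass ``rebound_s=None`` to re-estimate it as the
    first zero crossing after the minimum)."""
    t = diff_rate.times
    r = diff_rate.rate
    sel = (t >= 0) & (t <= search_window_s)
    if not sel.any():
        raise ValueError("no samples inside the minimum search window")
    seg = r[sel]
    t_seg = t[sel]
    at_min = np.isclose(seg, seg.min())
    idx = np.where(at_min)[0]
    t_min = float(t_seg[idx[(len(idx) - 1) // 2]])  # midpoint of the plateau

    half = peak_half_width_s
    peak_sel = (t >= t_min - half) & (t <= t_min + half)
    peak_inh = float(r[peak_sel].mean())

    if rebound_s is None:
        after = (t > t_min) & (r >= 0)
        rebound_s = float(t[after][0]) if after.any() else float(t[-1])
    win_sel = (t >= 0) & (t < rebound_s)
    window_mean = float(r[win_sel].mean()) if win_sel.any() else 0.0
    return InhibitionMetrics(
        peak_inhibition_hz=peak_inh,
        window_mean_inhibition_hz=window_mean,
        minimum_time_s=t_min,
        rebound_time_s=float(rebound_s),
    )
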