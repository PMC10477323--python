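"""Estimation of the individual pupillary dilation response function (IRF).

The pupil is treated as a linear time-invariant system.  Sudden decreases
in continuous illuminance provide a near-instantaneous neural input, so the
system's impulse response can be read off the illuminance responses:

1. each darkening segment is baseline-corrected by its first sample and
   rescaled by the predicted steady-state diameter difference between the
   illuminance levels before and after the change
   (``d(E) = C + A * exp(B * E)`` with ``A = 32.56``, ``B = -0.48`` per lx,
   ``C = -1.03`` in peak-normalized units);
2. segments are averaged and low-pass filtered at 4 Hz;
3. the time derivative of the mean response, zeroed after the trough that
   follows its maximum peak within the first 1.5 s, is fitted with a
   three-parameter gamma pdf (amplitude, scale, shape; onset fixed at 0)
   by ordinary least squares with a Nelder–Mead simplex search.

The fitted gamma is summarized by its temporal mean (shape x scale) and
excess kurtosis (6 / shape).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import GammaShape, SampledSeries, first_local_min, gamma_summary
from .preprocess import _lowpass

__all__ = [
    "SteadyStateModel",
    "IRFEstimate",
    "steady_state_diameter",
    "scale_darkening_segment",
    "mean_dilation_response",
    "fit_irf",
    "gamma_summary",
]


@dataclass(frozen=True)
class SteadyStateModel:
    """Exponential steady-state law for peak-normalized pupil diameter as
    a function of illuminance: ``d(E) = C + A * exp(B * E)``, ``B < 0``."""

    A: float = 32.56
    B: float = -0.48  # per lx
    C: float = -1.03

    def __post_init__(self) -> None:
        if self.B >= 0:
            raise ValueError("B must be negative: diameter decreases with illuminance")


def steady_state_diameter(E_v: float, model: SteadyStateModel | None = None) -> float:
    """Predicted steady-state peak-normalized diameter at illuminance
    ``E_v`` (lx)."""
    model = model or SteadyStateModel()
    return model.C + model.A * np.exp(model.B * np.asarray(E_v, dtype=float))


def scale_darkening_segment(
    segment: SampledSeries,
    E_before: float,
    E_after: float,
    model: SteadyStateModel | None = None,
) -> SampledSeries:
    """Baseline-correct a darkening segment by its first data point and
    divide by the predicted steady-state response difference
    ``d(E_after) - d(E_before)`` (positive for darkening)."""
    model = model or SteadyStateModel()
    divisor = steady_state_diameter(E_after, model) - steady_state_diameter(E_before, model)
    if divisor <= 0:
        raise ValueError(
            f"non-positive steady-state difference ({divisor:.4g}): "
            "illuminance pair is not a darkening"
        )
    out = segment.copy()
    out.values = (out.values - out.values[0]) / divisor
    return out


def mean_dilation_response(
    segments: list[SampledSeries], cutoff_hz: float = 4.0
) -> SampledSeries:
    """Pointwise mean over scaled segments, then 4 Hz low-pass.

    Invalid samples are excluded from the mean (per-sample counts are kept
    on the result as ``counts``)."""
    if not segments:
        raise ValueError("no segments supplied")
    length = len(segments[0])
    rate = segments[0].rate
    for s in segments:
        if len(s) != length or s.rate != rate:
            raise ValueError("segments must share length and rate")
    stack = np.vstack([s.values for s in segments])
    masks = np.vstack([s.valid for s in segments])
    stack = np.where(masks, stack, np.nan)
    counts = masks.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    valid = counts > 0
    if valid.any() and not valid.all():
        idx = np.arange(length)
        mean = np.interp(idx, idx[valid], mean[valid])
    smooth = _lowpass(mean, rate, cutoff_hz, pad_s=1.0)
    out = SampledSeries(smooth, rate, 0.0, valid)
    out.counts = counts
    return out


@dataclass
class IRFEstimate:
    """Result of the gamma fit to the mean-response derivative."""

    params: GammaShape
    rss: float
    derivative: SampledSeries  # zeroed target the gamma was fitted to
    fitted: np.ndarray
    converged: bool
    trough_index: int
    peak_index: int

    @property
    def mean(self) -> float:
        return self.params.mean

    @property
    def excess_kurtosis(self) -> float:
        return self.params.excess_kurtosis


def zeroed_derivative(
    mean_response: SampledSeries,
    peak_window_s: float = 1.5,
    trough_halfwidth_s: float = 0.1,
    localization_smooth_s: float = 0.15,
) -> tuple[SampledSeries, int, int]:
    """Time derivative of the mean response, zeroed from the trough that
    follows the maximum peak inside ``peak_window_s``.

    Peak and trough are localized on a boxcar-smoothed copy of the
    derivative (residual ripple above the 4 Hz cutoff would otherwise
    masquerade as the trough); the zeroing is applied to the raw
    derivative.  Returns ``(derivative, peak_index, trough_index)``.  If
    the derivative is monotone after the peak, the zeroing point falls on
    the global minimum after the peak (possibly the last sample, i.e. no
    zeroing)."""
    from scipy.ndimage import uniform_filter1d

    rate = mean_response.rate
    deriv = np.gradient(mean_response.values) * rate
    size = max(int(round(localization_smooth_s * rate)), 1)
    loc = uniform_filter1d(deriv, size=size, mode="nearest")
    n_peak = min(int(round(peak_window_s * rate)), len(deriv))
    if n_peak < 3:
        raise ValueError("mean response too short for peak search")
    peak = int(np.argmax(loc[:n_peak]))
    if loc[peak] <= 0:
        raise ValueError("no positive derivative peak inside the search window")
    trough = first_local_min(loc, peak, max(int(round(trough_halfwidth_s * rate)), 1))
    if trough is None:
        trough = peak + int(np.argmin(loc[peak:]))
    zeroed = deriv.copy()
    zeroed[trough:] = 0.0
    return (
        SampledSeries(zeroed, rate, mean_response.start, mean_response.valid.copy()),
        peak,
        trough,
    )


def _gamma_objective(target: np.ndarray, t: np.ndarray):
    from .core import _gamma_pdf

    def obj(p):
        log_k, log_theta, c = p
        model = c * _gamma_pdf(t, np.exp(log_k), np.exp(log_theta), 0.0)
        r = model - target
        return float(r @ r)

    return obj


def fit_irf(
    mean_response: SampledSeries,
    peak_window_s: float = 1.5,
    start_shapes: tuple[float, ...] = (0.5, 2.0, 8.0),
    start_scales: tuple[float, ...] = (0.05, 0.2, 0.8),
    maxiter: int = 5000,
) -> IRFEstimate:
    """Fit a gamma pdf (onset fixed at 0) to the zeroed derivative of the
    5 s mean dilation response.

    A deterministic 3x3 grid of (shape, scale) starting values guards
    against local minima; for this fit the solution is insensitive to the
    starting point.
    """
    deriv, peak, trough = zeroed_derivative(mean_response, peak_window_s)
    t = deriv.times - deriv.start
    target = deriv.values
    obj = _gamma_objective(target, t)

    area = float(np.trapezoid(np.clip(target, 0, None), t))
    c0 = area if area > 0 else 1.0
    best = None
    converged = False
    for k0 in start_shapes:
        for th0 in start_scales:
            res = optimize.minimize(
                obj,
                np.array([np.log(k0), np.log(th0), c0]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success)
    log_k, log_theta, c = best.x
    params = GammaShape(
        shape=float(np.exp(log_k)), scale=float(np.exp(log_theta)), amplitude=float(c)
    )
    fitted = params.density(t)
    return IRFEstimate(
        params=params,
        rss=float(best.fun),
        derivative=deriv,
        fitted=fitted,
        converged=converged,
        trough_index=trough,
        peak_index=peak,
    )
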