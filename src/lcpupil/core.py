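"""Core containers for uniformly sampled signals and gamma-shaped kernels.

The whole toolkit works on two simple objects:

* :class:`SampledSeries` — a uniformly sampled time series with a validity
  mask, the common currency for pupil-diameter and gaze channels.
* :class:`GammaShape` — a four-parameter gamma probability density
  (onset offset, shape, scale, amplitude) used both for the pupillary
  response function (IRF) and for the inferred neural input.

Summaries of a gamma kernel follow the standard identities for a gamma
distribution shifted by ``t0``: temporal mean ``k*theta + t0`` and excess
kurtosis ``6/k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

__all__ = ["SampledSeries", "GammaShape", "gamma_summary", "gamma_from_summary"]


@dataclass
class SampledSeries:
    """A uniformly sampled time series with a validity mask.

    Parameters
    ----------
    values :
        Sample values (arbitrary or normalized units).
    rate :
        Sampling rate in Hz. Must be positive.
    start :
        Time of the first sample in seconds.
    valid :
        Boolean mask, same length as ``values``. ``None`` means all valid.
    """

    values: np.ndarray
    rate: float
    start: float = 0.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(len(self.values)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate

    def copy(self) -> "SampledSeries":
        return SampledSeries(
            self.values.copy(), self.rate, self.start, self.valid.copy()
        )

    def index_of(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to range)."""
        i = int(round((t - self.start) * self.rate))
        return min(max(i, 0), len(self.values) - 1)

    def segment(self, t0: float, t1: float) -> "SampledSeries":
        """Sub-series covering ``[t0, t1)`` in absolute time."""
        i0 = int(np.ceil((t0 - self.start) * self.rate - 1e-9))
        i1 = int(np.ceil((t1 - self.start) * self.rate - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, len(self.values))
        if i1 <= i0:
            raise ValueError("empty segment requested")
        return SampledSeries(
            self.values[i0:i1],
            self.rate,
            self.start + i0 / self.rate,
            self.valid[i0:i1],
        )


@dataclass(frozen=True)
class GammaShape:
    """Gamma-pdf kernel ``c * (theta**k * Gamma(k))**-1 * (t - t0)**(k-1)
    * exp(-(t - t0)/theta)`` for ``t >= t0``, zero before.

    ``amplitude`` multiplies the *normalized* density, so the kernel
    integrates to ``amplitude`` over its support. For a pupillary response
    function the onset offset ``t0`` is fixed at zero; the inferred neural
    input allows ``t0`` up to 500 ms.
    """

    shape: float
    scale: float
    amplitude: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.t0 < 0:
            raise ValueError("offset t0 must be non-negative")

    @property
    def mean(self) -> float:
        """Temporal mean ``shape * scale + t0`` in seconds."""
        return self.shape * self.scale + self.t0

    @property
    def excess_kurtosis(self) -> float:
        """Excess kurtosis ``6 / shape`` of the gamma density."""
        return 6.0 / self.shape

    def density(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the (amplitude-scaled) density at times ``t``."""
        return self.amplitude * _gamma_pdf(
            np.asarray(t, dtype=float), self.shape, self.scale, self.t0
        )

    def cumulative(self, t: np.ndarray) -> np.ndarray:
        """Amplitude-scaled cumulative distribution at times ``t``."""
        from scipy.special import gammainc

        t = np.asarray(t, dtype=float)
        u = np.clip((t - self.t0) / self.scale, 0.0, None)
        return self.amplitude * gammainc(self.shape, u)

    def bin_mass(self, edges: np.ndarray) -> np.ndarray:
        """Amplitude-scaled probability mass per bin (CDF increments).

        The faithful discretization for convolution on a sample grid:
        unlike point-sampling the density, it stays exact for
        near-singular impulse-like kernels (shape << 1)."""
        return np.diff(self.cumulative(np.asarray(edges, dtype=float)))

    def with_amplitude(self, amplitude: float) -> "GammaShape":
        return replace(self, amplitude=amplitude)


def _gamma_pdf(t: np.ndarray, k: float, theta: float, t0: float) -> np.ndarray:
    """Normalized gamma pdf via log-space evaluation (stable for small k)."""
    x = t - t0
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    xp = x[pos]
    out[pos] = np.exp(
        (k - 1.0) * np.log(xp) - xp / theta - k * np.log(theta) - gammaln(k)
    )
    return out


def first_local_min(x: np.ndarray, start: int, order: int = 1) -> int | None:
    """First index after ``start`` that is the strict minimum of its
    ``+/-order``-sample neighborhood.  Guards trough detection against
    single-sample noise ripples; returns None when no such minimum exists
    (monotone tails, plateaus)."""
    n = len(x)
    for i in range(max(start, 1) + 1, n - 1):
        lo, hi = max(0, i - order), min(n, i + order + 1)
        seg = x[lo:hi]
        if x[i] <= seg.min() and np.sum(seg == x[i]) == 1:
            return i
    return None


def gamma_summary(params: GammaShape) -> tuple[float, float]:
    """Return ``(mean_time_s, excess_kurtosis)`` of a gamma kernel.

    mean = shape * scale + t0; excess kurtosis = 6 / shape.
    """
    return params.mean, params.excess_kurtosis


def gamma_from_summary(
    mean: float, excess_kurtosis: float, t0: float = 0.0, amplitude: float = 1.0
) -> GammaShape:
    """Invert the summary: unique ``(shape, scale)`` for a given mean
    (> t0) and excess kurtosis (> 0)."""
    if excess_kurtosis <= 0:
        raise ValueError("excess kurtosis must be positive")
    if mean <= t0:
        raise ValueError("mean must exceed the onset offset t0")
    k = 6.0 / excess_kurtosis
    theta = (mean - t0) / k
    return GammaShape(shape=k, scale=theta, amplitude=amplitude, t0=t0)
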