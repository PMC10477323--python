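"""Single-case inference: one individual's score against a small control
sample.

The point estimates follow the Crawford–Howell t form with standard-error
inflation ``sd * sqrt((n + 1) / n)``: the percent rank of the case within
the control population is the t CDF (df = n - 1) at that statistic, and the
one-tailed p is the corresponding tail probability.  These coincide with
the point estimates of the Bayesian single-case test of Crawford and
Garthwaite; a Monte-Carlo posterior backend is available for cross-checking
but the analytic form is the default because it is deterministic.

Also provided: step-down Holm adjustment for the two-test families used in
the pupillometry analyses (response mean time, excess kurtosis), and a
Kolmogorov–Smirnov normality screen for the control sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ControlSummary",
    "SingleCaseResult",
    "crawford_test",
    "holm_adjust",
    "ks_normality",
]


@dataclass(frozen=True)
class ControlSummary:
    """Summary of the control sample: size, mean and SD (ddof=1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("control sample must have n >= 2")
        if self.sd <= 0:
            raise ValueError("control SD must be positive")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "ControlSummary":
        values = np.asarray(values, dtype=float)
        return cls(n=len(values), mean=float(np.mean(values)), sd=float(np.std(values, ddof=1)))


@dataclass(frozen=True)
class SingleCaseResult:
    """Outcome of a single-case comparison.

    ``percent_rank`` is the point estimate of the percentage of the control
    population scoring *below* the case; ``p_one_tailed`` is the probability
    of a control more extreme than the case in the direction of the
    deviation.  The two satisfy ``percent_rank/100 + p = 1`` for a case
    above the control mean and ``percent_rank/100 = p`` below it.
    """

    case: float
    t: float
    df: int
    percent_rank: float
    p_one_tailed: float
    direction: str  # "above" or "below" the control mean


def crawford_test(
    case: float,
    controls: ControlSummary | np.ndarray,
    method: str = "analytic",
    n_draws: int = 1_000_000,
    seed: int | None = None,
) -> SingleCaseResult:
    """Compare one case value against a control sample.

    Parameters
    ----------
    case :
        The single case's score.
    controls :
        A :class:`ControlSummary` or an array of raw control values.
    method :
        ``"analytic"`` (default; Crawford–Howell t form) or
        ``"montecarlo"`` (Bayesian posterior simulation; converges to the
        analytic point estimate as ``n_draws`` grows).
    """
    if not isinstance(controls, ControlSummary):
        controls = ControlSummary.from_values(np.asarray(controls))
    n, m, sd = controls.n, controls.mean, controls.sd
    df = n - 1
    t = (case - m) / (sd * np.sqrt((n + 1.0) / n))

    if method == "analytic":
        frac_below = float(stats.t.cdf(t, df))
        tail_above = float(stats.t.sf(t, df))  # avoids 1 - cdf cancellation
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        # Posterior with the standard non-informative prior:
        # sigma^2 ~ (n-1) s^2 / chi2_{n-1},  mu | sigma ~ N(m, sigma^2/n)
        chi2 = rng.chisquare(df, size=n_draws)
        sigma = np.sqrt(df * sd**2 / chi2)
        mu = rng.normal(m, sigma / np.sqrt(n))
        frac_below = float(np.mean(stats.norm.cdf((case - mu) / sigma)))
        tail_above = 1.0 - frac_below
    else:
        raise ValueError(f"unknown method {method!r}")

    direction = "above" if case >= m else "below"
    p = tail_above if direction == "above" else frac_below
    return SingleCaseResult(
        case=float(case),
        t=float(t),
        df=df,
        percent_rank=100.0 * frac_below,
        p_one_tailed=p,
        direction=direction,
    )


def holm_adjust(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment, order of the input preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="holm")[1]


def ks_normality(values: np.ndarray) -> tuple[float, float, dict]:
    """One-sample Kolmogorov–Smirnov test against a normal with the sample
    mean and SD.

    Returns ``(statistic, p, info)``.  ``info["parameters_estimated"]`` is
    always True: the reference normal uses plug-in estimates, so the
    asymptotic p-value is conservative relative to a Lilliefors-corrected
    test.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values")
    sd = np.std(values, ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = stats.kstest(values, "norm", args=(np.mean(values), sd))
    return float(stat), float(p), {"parameters_estimated": True}
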