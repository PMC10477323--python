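"""Synthetic two-eye recordings with the statistical structure the
analysis assumes.

The generator emulates the two study paradigms:

* a continuous-illuminance task (five sessions of 24 trials; circles at
  four illuminance levels on a 7.30 lx background, giving 24 darkening
  and 24 brightening changes per session), whose steady-state pupil
  levels follow the exponential law ``d(E) = C + A exp(B E)`` and whose
  transitions are shaped by a known gamma response function;
* an auditory oddball task (30 oddballs among 120 standards, 2 s ISI),
  whose event-locked dilations are the convolution of a known gamma
  neural input with the response function.

Measurement noise, slow drift, blink gaps with edge artifacts, fixational
gaze drift and injected microsaccades (with post-stimulus rate
inhibition) complete the picture.  Ground truth sufficient to score
recovery is attached to every recording; a given seed fully determines
the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import GammaShape, SampledSeries
from .irf import SteadyStateModel, steady_state_diameter

__all__ = [
    "IlluminanceEvent",
    "IlluminanceSchedule",
    "OddballSchedule",
    "SimulationConfig",
    "SimulatedRecording",
    "make_illuminance_schedule",
    "make_oddball_schedule",
    "simulate_pupil",
    "simulate_gaze",
    "simulate_recording",
]

DEFAULT_LEVELS = (
    ("black", 5.30),
    ("dark_gray", 5.80),
    ("light_gray", 9.60),
    ("white", 13.30),
)
BACKGROUND_LX = 7.30


@dataclass(frozen=True)
class IlluminanceEvent:
    time: float
    E_before: float
    E_after: float
    direction: str  # "darkening" or "brightening"


@dataclass
class IlluminanceSchedule:
    session_count: int
    trials_per_session: int
    rest_duration: float
    circle_duration: float
    gap_duration: float
    levels: tuple
    background_lx: float
    events: list[IlluminanceEvent]
    session_starts: list[float]
    duration: float

    @property
    def darkening_events(self) -> list[IlluminanceEvent]:
        return [e for e in self.events if e.direction == "darkening"]

    @property
    def brightening_events(self) -> list[IlluminanceEvent]:
        return [e for e in self.events if e.direction == "brightening"]


@dataclass
class OddballSchedule:
    events: list[tuple[float, str]]  # (time_s, "standard" | "oddball")
    isi: float

    @property
    def oddball_times(self) -> list[float]:
        return [t for t, lab in self.events if lab == "oddball"]

    @property
    def standard_times(self) -> list[float]:
        return [t for t, lab in self.events if lab == "standard"]

    @property
    def duration(self) -> float:
        return self.events[-1][0] if self.events else 0.0


def make_illuminance_schedule(
    session_count: int = 5,
    trials_per_session: int = 24,
    rest_duration: float = 45.0,
    circle_duration: float = 5.0,
    gap_duration: float = 5.0,
    levels: tuple = DEFAULT_LEVELS,
    background_lx: float = BACKGROUND_LX,
    seed: int = 0,
) -> IlluminanceSchedule:
    """Randomized continuous-illuminance schedule.

    Each trial contributes two illuminance changes (circle appearance and
    disappearance); with the default levels every session yields 24
    darkening and 24 brightening events."""
    if min(rest_duration, circle_duration, gap_duration) <= 0:
        raise ValueError("durations must be positive")
    if not levels:
        raise ValueError("level list must be non-empty")
    if trials_per_session % len(levels) != 0:
        raise ValueError(
            f"{trials_per_session} trials per session not divisible by "
            f"{len(levels)} levels"
        )
    reps = trials_per_session // len(levels)
    rng = np.random.default_rng(seed)
    events: list[IlluminanceEvent] = []
    session_starts = []
    t = 0.0
    for _ in range(session_count):
        session_starts.append(t)
        order = np.repeat(np.arange(len(levels)), reps)
        rng.shuffle(order)
        t += rest_duration
        for li in order:
            _, lx = levels[li]
            appear_dir = "darkening" if lx < background_lx else "brightening"
            disappear_dir = "brightening" if lx < background_lx else "darkening"
            events.append(IlluminanceEvent(t, background_lx, lx, appear_dir))
            t += circle_duration
            events.append(IlluminanceEvent(t, lx, background_lx, disappear_dir))
            t += gap_duration
    return IlluminanceSchedule(
        session_count=session_count,
        trials_per_session=trials_per_session,
        rest_duration=rest_duration,
        circle_duration=circle_duration,
        gap_duration=gap_duration,
        levels=tuple(levels),
        background_lx=background_lx,
        events=events,
        session_starts=session_starts,
        duration=t,
    )


def make_oddball_schedule(
    n_oddball: int = 30,
    n_standard: int = 120,
    isi: float = 2.0,
    seed: int = 0,
    allow_adjacent: bool = False,
) -> OddballSchedule:
    """Oddball/standard tone schedule at a fixed inter-stimulus interval.

    Oddball positions are sampled uniformly under the (default)
    no-two-consecutive-oddballs constraint via the standard stars-and-bars
    bijection."""
    if n_oddball < 0 or n_standard < 0:
        raise ValueError("tone counts must be non-negative")
    if isi <= 0:
        raise ValueError("isi must be positive")
    n_total = n_oddball + n_standard
    rng = np.random.default_rng(seed)
    if allow_adjacent or n_oddball == 0:
        positions = rng.choice(n_total, size=n_oddball, replace=False)
    else:
        if n_oddball > n_standard + 1:
            raise ValueError(
                "cannot place oddballs without adjacency: too few standards"
            )
        base = np.sort(rng.choice(n_total - n_oddball + 1, size=n_oddball, replace=False))
        positions = base + np.arange(n_oddball)
    odd = set(int(p) for p in positions)
    events = [
        (i * isi, "oddball" if i in odd else "standard") for i in range(n_total)
    ]
    return OddballSchedule(events=events, isi=isi)


@dataclass
class SimulationConfig:
    """All generating parameters of the synthetic recordings.

    Pupil works in mm around a 2.82 mm baseline (the control-sample
    baseline diameter); ``mm_per_norm`` converts the peak-normalized
    steady-state law into mm.  The default truths mirror control-like
    subjects: IRF mean 600 ms (shape 2.5), oddball input mean ~657 ms with
    excess kurtosis ~2.5, no input to standard tones.  Brightening
    transitions use a separate (constriction) gamma shape, which the
    analysis never models."""

    irf_truth: GammaShape = field(
        default_factory=lambda: GammaShape(shape=2.5, scale=0.24, amplitude=1.0)
    )
    input_truth: GammaShape = field(
        default_factory=lambda: GammaShape(
            shape=2.388, scale=0.27487, amplitude=0.12, t0=0.0005
        )
    )
    standard_input: GammaShape | None = None
    constriction_truth: GammaShape = field(
        default_factory=lambda: GammaShape(shape=2.0, scale=0.15, amplitude=1.0)
    )
    steady_state: SteadyStateModel = field(default_factory=SteadyStateModel)
    baseline_mm: float = 2.82
    mm_per_norm: float = 0.35
    noise_sd: float = 0.01  # mm, white, per eye
    drift_amplitude_mm: float = 0.03
    drift_timescale_s: float = 60.0
    blink_rate_per_min: float = 6.0
    blink_duration_range_s: tuple[float, float] = (0.1, 0.3)
    blink_edge_spike_mm: float = 0.8
    rate_hz: float = 500.0
    # gaze / microsaccades
    ms_base_rate_hz: float = 1.2
    ms_inhibition_depth: float = 0.7  # fraction of the base rate suppressed
    ms_inhibition_window_s: tuple[float, float] = (0.0, 0.35)
    ms_amplitude_median_deg: float = 0.4
    ms_amplitude_log_sd: float = 0.35
    ms_amplitude_fixed_deg: float | None = None
    main_sequence_slope: float = 100.0  # peak velocity (deg/s) per deg
    gaze_drift_diffusion: float = 0.06  # deg / sqrt(s)
    gaze_drift_tau_s: float = 1.0
    gaze_noise_sd_deg: float = 0.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.rate_hz <= 0 or self.drift_timescale_s <= 0:
            raise ValueError("rates and timescales must be positive")
        if self.blink_rate_per_min < 0 or self.ms_base_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        lo, hi = self.blink_duration_range_s
        if not (0 < lo <= hi):
            raise ValueError("invalid blink duration range")
        if not (0 <= self.ms_inhibition_depth <= 1):
            raise ValueError("inhibition depth must lie in [0, 1]")


@dataclass
class SimulatedRecording:
    """Two-eye pupil (mm) and gaze (deg) channels with event markers and
    the full generating ground truth."""

    pupil_left: SampledSeries | None
    pupil_right: SampledSeries | None
    gaze_x: SampledSeries | None
    gaze_y: SampledSeries | None
    events: list
    ground_truth: dict
    rate: float


def _unit(g: GammaShape) -> GammaShape:
    return g.with_amplitude(1.0)


def _event_times_and_kinds(schedule):
    if isinstance(schedule, OddballSchedule):
        return [(t, lab) for t, lab in schedule.events]
    return [(e.time, e.direction) for e in schedule.events]


def simulate_pupil(
    schedule,
    config: SimulationConfig | None = None,
    seed: int = 0,
    lead_in_s: float = 5.0,
    tail_s: float = 6.0,
) -> SimulatedRecording:
    """Forward-simulate the binocular pupil trace for a schedule.

    The shared signal is the baseline plus (for illuminance schedules) the
    steady-state track whose transitions are shaped by the cumulative
    response function, plus (for tone schedules) the convolution of the
    gamma input with the unit-area response function at each tone, plus
    slow sinusoidal drift.  Each eye adds independent white noise; blinks
    open simultaneous gaps in both eyes with brief edge spikes."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    rate = config.rate_hz
    dt = 1.0 / rate

    ev = _event_times_and_kinds(schedule)
    if not ev:
        raise ValueError("schedule has no events")
    times_ev = [t for t, _ in ev]
    if np.any(np.diff(times_ev) < dt):
        raise ValueError("event spacing shorter than one sample")

    start = times_ev[0] - lead_in_s
    duration = (times_ev[-1] + tail_s) - start
    n = int(round(duration * rate))
    t = start + np.arange(n) * dt

    shared = np.full(n, config.baseline_mm)

    if isinstance(schedule, OddballSchedule):
        templates = {}
        tt = np.arange(int(round(6.0 * rate))) * dt
        edges = np.arange(len(tt) + 1) * dt
        irf_k = _unit(config.irf_truth).density(tt)
        for label, truth in (
            ("oddball", config.input_truth),
            ("standard", config.standard_input),
        ):
            if truth is None:
                continue
            templates[label] = np.convolve(truth.bin_mass(edges), irf_k)[: len(tt)]
        for te, label in ev:
            tpl = templates.get(label)
            if tpl is None:
                continue
            i0 = int(round((te - start) * rate))
            sl = min(len(tpl), n - i0)
            shared[i0 : i0 + sl] += tpl[:sl]
    else:
        tt = np.arange(int(round(6.0 * rate))) * dt
        cum_dil = _unit(config.irf_truth).cumulative(tt)
        cum_con = _unit(config.constriction_truth).cumulative(tt)
        for e in schedule.events:
            delta = steady_state_diameter(
                e.E_after, config.steady_state
            ) - steady_state_diameter(e.E_before, config.steady_state)
            cum = cum_dil if e.direction == "darkening" else cum_con
            i0 = int(round((e.time - start) * rate))
            sl = min(len(tt), n - i0)
            shared[i0 : i0 + sl] += config.mm_per_norm * delta * cum[:sl]
            if i0 + sl < n:
                shared[i0 + sl :] += config.mm_per_norm * delta

    phase = rng.uniform(0, 2 * np.pi)
    if config.drift_amplitude_mm > 0:
        shared = shared + config.drift_amplitude_mm * np.sin(
            2 * np.pi * (t - start) / config.drift_timescale_s + phase
        )

    left = shared + rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else shared.copy()
    right = shared + rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else shared.copy()
    valid = np.ones(n, dtype=bool)

    blinks = []
    n_blinks = rng.poisson(config.blink_rate_per_min * duration / 60.0)
    edge = max(int(round(0.01 * rate)), 1)
    for _ in range(n_blinks):
        b0 = rng.uniform(0, duration)
        dur = rng.uniform(*config.blink_duration_range_s)
        i0 = int(b0 * rate)
        i1 = min(int((b0 + dur) * rate), n)
        if i1 <= i0:
            continue
        blinks.append((start + i0 * dt, start + i1 * dt))
        for arr in (left, right):
            ramp = np.linspace(0, config.blink_edge_spike_mm, edge)
            lo = max(0, i0 - edge)
            arr[lo:i0] -= ramp[edge - (i0 - lo) :]
            hi = min(n, i1 + edge)
            arr[i1:hi] -= ramp[::-1][: hi - i1]
            arr[i0:i1] = np.nan
        valid[i0:i1] = False

    markers = _markers(schedule)
    gt = {
        "kind": "oddball" if isinstance(schedule, OddballSchedule) else "illuminance",
        "seed": seed,
        "config": _config_dict(config),
        "event_times": times_ev,
        "blinks": blinks,
    }
    return SimulatedRecording(
        pupil_left=SampledSeries(left, rate, start, valid.copy()),
        pupil_right=SampledSeries(right, rate, start, valid.copy()),
        gaze_x=None,
        gaze_y=None,
        events=markers,
        ground_truth=gt,
        rate=rate,
    )


def simulate_gaze(
    schedule,
    config: SimulationConfig | None = None,
    seed: int = 0,
    lead_in_s: float = 5.0,
    tail_s: float = 6.0,
) -> SimulatedRecording:
    """Fixational gaze: mean-reverting (Ornstein–Uhlenbeck) drift around
    fixation plus microsaccades from an inhomogeneous Poisson process
    whose rate dips after stimulus onsets.

    Each injected microsaccade has a raised-cosine velocity profile with
    peak velocity = main-sequence slope x amplitude; injected onsets,
    amplitudes and peak velocities are stored as ground truth."""
    config = config or SimulationConfig()
    config.validate()
    isi = getattr(schedule, "isi", None)
    win0, win1 = config.ms_inhibition_window_s
    if isi is not None and (win1 - win0) > isi:
        raise ValueError("inhibition window exceeds the inter-stimulus interval")
    rng = np.random.default_rng(seed)
    rate = config.rate_hz
    dt = 1.0 / rate

    ev = _event_times_and_kinds(schedule)
    times_ev = np.array([t for t, _ in ev])
    start = times_ev[0] - lead_in_s
    duration = (times_ev[-1] + tail_s) - start
    n = int(round(duration * rate))
    t = start + np.arange(n) * dt

    # OU drift, one shared binocular signal per axis
    gx = np.zeros(n)
    gy = np.zeros(n)
    sq = config.gaze_drift_diffusion * np.sqrt(dt)
    steps = rng.normal(0.0, 1.0, size=(2, n))
    decay = 1.0 - dt / config.gaze_drift_tau_s
    for i in range(1, n):
        gx[i] = gx[i - 1] * decay + sq * steps[0, i]
        gy[i] = gy[i - 1] * decay + sq * steps[1, i]

    # inhomogeneous Poisson microsaccades via thinning
    def rel_rate(tc: float) -> float:
        if config.ms_inhibition_depth <= 0:
            return 1.0
        k = np.searchsorted(times_ev, tc) - 1
        if k >= 0 and win0 <= tc - times_ev[k] <= win1:
            return 1.0 - config.ms_inhibition_depth
        return 1.0

    injected = []
    if config.ms_base_rate_hz > 0:
        n_cand = rng.poisson(config.ms_base_rate_hz * duration)
        cand = np.sort(rng.uniform(start, start + duration, n_cand))
        accept = rng.uniform(size=n_cand)
        last = -np.inf
        for tc, u in zip(cand, accept):
            if u >= rel_rate(tc):
                continue
            if tc - last < 0.025:
                continue
            if config.ms_amplitude_fixed_deg is not None:
                amp = config.ms_amplitude_fixed_deg
                rng.normal()  # keep the stream aligned with the sampled branch
            else:
                amp = config.ms_amplitude_median_deg * np.exp(
                    rng.normal(0.0, config.ms_amplitude_log_sd)
                )
            theta = rng.uniform(0, 2 * np.pi)
            pv = config.main_sequence_slope * amp
            dur = 2.0 * amp / pv  # raised cosine: mean velocity = pv / 2
            m = max(int(round(dur * rate)), 4)
            u_prof = np.arange(1, m + 1) / m
            profile = u_prof - np.sin(2 * np.pi * u_prof) / (2 * np.pi)
            i0 = int(round((tc - start) * rate))
            if i0 + m >= n:
                continue
            dx = amp * np.cos(theta)
            dy = amp * np.sin(theta)
            gx[i0 : i0 + m] += dx * profile
            gx[i0 + m :] += dx
            gy[i0 : i0 + m] += dy * profile
            gy[i0 + m :] += dy
            injected.append(
                {"onset": float(tc), "amplitude": float(amp), "peak_velocity": float(pv),
                 "duration": float(m * dt)}
            )
            last = tc

    if config.gaze_noise_sd_deg > 0:
        gx = gx + rng.normal(0, config.gaze_noise_sd_deg, n)
        gy = gy + rng.normal(0, config.gaze_noise_sd_deg, n)

    gt = {
        "kind": "gaze",
        "seed": seed,
        "config": _config_dict(config),
        "microsaccades": injected,
        "event_times": times_ev.tolist(),
    }
    return SimulatedRecording(
        pupil_left=None,
        pupil_right=None,
        gaze_x=SampledSeries(gx, rate, start),
        gaze_y=SampledSeries(gy, rate, start),
        events=_markers(schedule),
        ground_truth=gt,
        rate=rate,
    )


def simulate_recording(
    schedule,
    config: SimulationConfig | None = None,
    seed: int = 0,
    lead_in_s: float = 5.0,
    tail_s: float = 6.0,
) -> SimulatedRecording:
    """Full recording: pupil and gaze channels from independent substreams
    of the same seed; blink gaps are applied to both modalities."""
    config = config or SimulationConfig()
    rec_p = simulate_pupil(schedule, config, _sub_seed(seed, 0), lead_in_s, tail_s)
    rec_g = simulate_gaze(schedule, config, _sub_seed(seed, 1), lead_in_s, tail_s)
    for ch in (rec_g.gaze_x, rec_g.gaze_y):
        m = min(len(ch), len(rec_p.pupil_left))
        ch.valid[:m] &= rec_p.pupil_left.valid[:m]
    gt = dict(rec_p.ground_truth)
    gt["microsaccades"] = rec_g.ground_truth["microsaccades"]
    return SimulatedRecording(
        pupil_left=rec_p.pupil_left,
        pupil_right=rec_p.pupil_right,
        gaze_x=rec_g.gaze_x,
        gaze_y=rec_g.gaze_y,
        events=rec_p.events,
        ground_truth=gt,
        rate=config.rate_hz,
    )


def _sub_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def _markers(schedule):
    if isinstance(schedule, OddballSchedule):
        return [(t, "tone", lab) for t, lab in schedule.events]
    return [(e.time, "illuminance", e.E_after) for e in schedule.events]


def _config_dict(config: SimulationConfig) -> dict:
    out = {}
    for key, val in asdict(config).items():
        if isinstance(val, tuple):
            val = list(val)
        out[key] = val
    return out
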