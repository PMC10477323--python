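"""Schedules and the forward simulators: invariants, determinism, and
ground-truth consistency."""

import itertools

import numpy as np
import pytest

from lcpupil.core import GammaShape, SampledSeries
from lcpupil.synthetic import (
    SimulationConfig,
    make_illuminance_schedule,
    make_oddball_schedule,
    simulate_gaze,
    simulate_pupil,
    simulate_recording,
)


class TestIlluminanceSchedule:
    def test_default_counts(self):
        sched = make_illuminance_schedule(seed=1)
        assert len(sched.events) == 240  # 120 trials x 2 changes
        assert len(sched.darkening_events) == 120
        assert len(sched.brightening_events) == 120
        per_session = 24 * 2
        for s in range(5):
            chunk = sched.events[s * per_session : (s + 1) * per_session]
            assert sum(e.direction == "darkening" for e in chunk) == 24

    def test_event_times_strictly_increasing(self):
        sched = make_illuminance_schedule(seed=2)
        times = [e.time for e in sched.events]
        assert np.all(np.diff(times) > 0)

    def test_single_black_level(self):
        sched = make_illuminance_schedule(
            session_count=1, trials_per_session=6, levels=(("black", 5.30),), seed=0
        )
        assert len(sched.darkening_events) == 6  # appearances
        assert len(sched.brightening_events) == 6  # disappearances

    def test_deterministic_under_seed(self):
        a = make_illuminance_schedule(seed=9)
        b = make_illuminance_schedule(seed=9)
        assert a.events == b.events

    def test_indivisible_trial_count_rejected(self):
        with pytest.raises(ValueError):
            make_illuminance_schedule(trials_per_session=25)


class TestOddballSchedule:
    def test_default_counts_and_span(self):
        sched = make_oddball_schedule(seed=7)
        assert len(sched.events) == 150
        assert len(sched.oddball_times) == 30
        assert sched.events[-1][0] == pytest.approx(298.0)

    def test_zero_oddballs(self):
        sched = make_oddball_schedule(n_oddball=0, n_standard=10)
        assert all(lab == "standard" for _, lab in sched.events)

    def test_no_adjacent_oddballs_exhaustive(self):
        """Brute-force adjacency check over many seeds at small n."""
        for seed in range(50):
            sched = make_oddball_schedule(n_oddball=5, n_standard=5, seed=seed)
            labels = [lab for _, lab in sched.events]
            assert not any(
                a == b == "oddball" for a, b in itertools.pairwise(labels)
            )

    def test_unsatisfiable_constraint_rejected(self):
        with pytest.raises(ValueError):
            make_oddball_schedule(n_oddball=7, n_standard=5)


class TestSimulatePupil:
    def test_noiseless_trace_equals_analytic_convolution(self):
        """Single oddball, no noise: the trace minus baseline equals the
        convolution of the gamma input with the response function."""
        cfg = SimulationConfig(
            noise_sd=0.0, blink_rate_per_min=0.0, drift_amplitude_mm=0.0
        )
        cfg.input_truth = GammaShape(shape=3.0, scale=0.2, amplitude=1.0, t0=0.1)
        sched = make_oddball_schedule(n_oddball=1, n_standard=0, allow_adjacent=True)
        rec = simulate_pupil(sched, cfg, seed=0)
        rate = cfg.rate_hz
        i0 = rec.pupil_left.index_of(0.0)
        got = rec.pupil_left.values[i0 : i0 + int(4 * rate)] - cfg.baseline_mm
        t = np.arange(int(4 * rate)) / rate
        edges = np.arange(len(t) + 1) / rate
        expected = np.convolve(
            cfg.input_truth.bin_mass(edges),
            cfg.irf_truth.with_amplitude(1.0).density(t),
        )[: len(t)]
        assert np.allclose(got, expected, atol=1e-9)

    def test_zero_amplitude_input_gives_flat_trace(self):
        cfg = SimulationConfig(
            noise_sd=0.0, blink_rate_per_min=0.0, drift_amplitude_mm=0.0
        )
        cfg.standard_input = None
        cfg.input_truth = GammaShape(shape=2.0, scale=0.2, amplitude=0.0)
        sched = make_oddball_schedule(n_oddball=2, n_standard=6, seed=1)
        rec = simulate_pupil(sched, cfg, seed=1)
        assert np.allclose(rec.pupil_left.values, cfg.baseline_mm)

    def test_bit_identical_under_seed(self):
        sched = make_oddball_schedule(n_oddball=3, n_standard=9, seed=5)
        a = simulate_recording(sched, SimulationConfig(), seed=5)
        b = simulate_recording(sched, SimulationConfig(), seed=5)
        assert np.array_equal(a.pupil_left.values, b.pupil_left.values, equal_nan=True)
        assert np.array_equal(a.gaze_x.values, b.gaze_x.values)
        assert np.array_equal(a.pupil_left.valid, b.pupil_left.valid)

    def test_blink_gaps_shared_between_eyes(self):
        cfg = SimulationConfig(blink_rate_per_min=30.0)
        sched = make_oddball_schedule(n_oddball=2, n_standard=6, seed=2)
        rec = simulate_pupil(sched, cfg, seed=2)
        assert (~rec.pupil_left.valid).any()
        assert np.array_equal(rec.pupil_left.valid, rec.pupil_right.valid)
        assert np.isnan(rec.pupil_left.values[~rec.pupil_left.valid]).all()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-0.1).validate()

    def test_illuminance_steady_state_levels(self):
        """Long after a darkening change the trace sits at the new
        steady-state level predicted by the exponential law."""
        from lcpupil.irf import steady_state_diameter

        cfg = SimulationConfig(
            noise_sd=0.0, blink_rate_per_min=0.0, drift_amplitude_mm=0.0
        )
        sched = make_illuminance_schedule(
            session_count=1, trials_per_session=4, circle_duration=5.0, seed=0
        )
        rec = simulate_pupil(sched, cfg, seed=0)
        e = sched.events[0]
        delta = steady_state_diameter(e.E_after, cfg.steady_state) - steady_state_diameter(
            e.E_before, cfg.steady_state
        )
        i = rec.pupil_left.index_of(e.time + 4.9)
        expected = cfg.baseline_mm + cfg.mm_per_norm * delta
        assert rec.pupil_left.values[i] == pytest.approx(expected, abs=0.01)


class TestSimulateGaze:
    def test_poisson_count_within_three_sigma(self):
        cfg = SimulationConfig(ms_base_rate_hz=1.0, ms_inhibition_depth=0.0)
        sched = make_oddball_schedule(seed=1)  # ~300 s
        rec = simulate_gaze(sched, cfg, seed=1)
        duration = len(rec.gaze_x) / cfg.rate_hz
        lam = cfg.ms_base_rate_hz * duration
        count = len(rec.ground_truth["microsaccades"])
        assert abs(count - lam) < 3.5 * np.sqrt(lam)

    def test_total_inhibition_empties_post_tone_windows(self):
        cfg = SimulationConfig(
            ms_inhibition_depth=1.0, ms_inhibition_window_s=(0.0, 0.3)
        )
        sched = make_oddball_schedule(seed=2)
        rec = simulate_gaze(sched, cfg, seed=2)
        tone_times = np.array([t for t, _ in sched.events])
        for ev in rec.ground_truth["microsaccades"]:
            k = np.searchsorted(tone_times, ev["onset"]) - 1
            if k >= 0:
                rel = ev["onset"] - tone_times[k]
                assert not (0.0 <= rel <= 0.3)

    def test_inhibition_window_longer_than_isi_rejected(self):
        cfg = SimulationConfig(ms_inhibition_window_s=(0.0, 3.0))
        sched = make_oddball_schedule(seed=0)
        with pytest.raises(ValueError):
            simulate_gaze(sched, cfg, seed=0)

    def test_main_sequence_respected(self):
        cfg = SimulationConfig(ms_amplitude_fixed_deg=0.5, ms_inhibition_depth=0.0)
        sched = make_oddball_schedule(n_oddball=5, n_standard=15, seed=3)
        rec = simulate_gaze(sched, cfg, seed=3)
        for ev in rec.ground_truth["microsaccades"]:
            assert ev["peak_velocity"] == pytest.approx(
                cfg.main_sequence_slope * ev["amplitude"]
            )


class TestRecordingRoundTrip:
    def test_io_round_trip(self, tmp_path):
        from lcpupil.io import read_events, read_ground_truth, read_samples, write_recording

        sched = make_oddball_schedule(n_oddball=2, n_standard=6, seed=4)
        rec = simulate_recording(sched, SimulationConfig(), seed=4)
        paths = write_recording(rec, tmp_path)
        ch = read_samples(paths["samples"])
        assert ch["pupil_left"].rate == pytest.approx(rec.rate, rel=1e-3)
        valid = rec.pupil_left.valid
        assert np.allclose(
            ch["pupil_left"].values[valid], rec.pupil_left.values[valid], atol=1e-5
        )
        events = read_events(paths["events"])
        assert len(events) == 8
        gt = read_ground_truth(paths["truth"])
        assert gt["seed"] == rec.ground_truth["seed"]

    def test_downstream_recovery_of_input_mean(self, wave_input):
        """Defaults at one seed: the fitted neural-input mean lands
        within 15% of the generating truth."""
        from lcpupil.neural_input import build_difference_response, fit_input
        from lcpupil.preprocess import (
            CleaningParams,
            clean_and_combine,
            extract_trials,
            normalize_session,
        )

        cfg = SimulationConfig()
        sched = make_oddball_schedule(seed=11)
        rec = simulate_pupil(sched, cfg, seed=11)
        cleaned, _ = clean_and_combine(rec.pupil_left, rec.pupil_right, CleaningParams())
        cleaned = normalize_session(cleaned)
        diff = build_difference_response(
            extract_trials(cleaned, sched.oddball_times),
            extract_trials(cleaned, sched.standard_times),
        )
        fit = fit_input(diff, cfg.irf_truth, n_starts=60, seed=11)
        assert fit.mean == pytest.approx(cfg.input_truth.mean, rel=0.15)
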