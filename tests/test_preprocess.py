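"""Validity pass, combination, filtering, gap interpolation, fixation
exclusion, normalization and baseline extraction."""

import numpy as np
import pytest

from lcpupil.core import SampledSeries
from lcpupil.preprocess import (
    CleaningParams,
    FixationParams,
    _validity_pass,
    baseline_diameter,
    clean_and_combine,
    exclude_off_fixation,
    extract_trials,
    normalize_session,
)

RATE = 500.0


def pair(values, valid=None):
    return (
        SampledSeries(values.copy(), RATE, 0.0, None if valid is None else valid.copy()),
        SampledSeries(values.copy(), RATE, 0.0, None if valid is None else valid.copy()),
    )


class TestCleanAndCombine:
    def test_constant_passthrough(self):
        left, right = pair(np.full(5000, 3.0))
        out, report = clean_and_combine(left, right)
        assert out.rate == 1000.0
        assert len(out) == 10000
        # interior samples, away from filter edges
        assert np.allclose(out.values[1000:-1000], 3.0, atol=1e-6)
        assert not report.all_invalid

    def test_gap_rule_200_vs_300_ms(self):
        valid = np.ones(5000, bool)
        valid[1000:1100] = False  # 200 ms
        valid[3000:3150] = False  # 300 ms
        left, right = pair(np.full(5000, 3.0), valid)
        out, _ = clean_and_combine(left, right)
        assert out.valid[2000:2200].all(), "200 ms gap must be interpolated"
        assert np.allclose(out.values[2000:2200], 3.0, atol=1e-3)
        assert (~out.valid[6000:6300]).any(), "300 ms gap must stay invalid"
        assert (~out.valid[6100:6200]).all()
        assert np.isnan(out.values[~out.valid]).all()

    def test_single_sample_spike_removed_by_speed_gate(self):
        vals = np.full(5000, 3.0)
        vals[2500] = 8.0  # +5 mm within the range gate, implausibly fast
        left, right = pair(vals)
        out, _ = clean_and_combine(left, right)
        assert abs(out.values[5000] - 3.0) < 0.01

    def test_out_of_range_samples_rejected(self):
        vals = np.full(5000, 3.0)
        vals[100:200] = 12.0  # beyond the 9 mm gate
        left, right = pair(vals)
        _, report = clean_and_combine(left, right)
        assert report.fractions["left"]["range"] > 0

    def test_all_invalid_flagged_not_raised(self):
        left, right = pair(np.full(1000, 3.0), np.zeros(1000, bool))
        out, report = clean_and_combine(left, right)
        assert report.all_invalid
        assert not out.valid.any()

    def test_mismatched_rates_rejected(self):
        a = SampledSeries(np.full(100, 3.0), 500.0)
        b = SampledSeries(np.full(100, 3.0), 250.0)
        with pytest.raises(ValueError):
            clean_and_combine(a, b)

    def test_one_eye_gap_filled_from_other(self):
        valid_l = np.ones(5000, bool)
        valid_l[2000:2400] = False  # 800 ms gone in the left eye only
        left = SampledSeries(np.full(5000, 3.0), RATE, 0.0, valid_l)
        right = SampledSeries(np.full(5000, 3.2), RATE, 0.0)
        out, _ = clean_and_combine(left, right)
        assert out.valid.all()

    def test_validity_pass_is_stable(self):
        """The validity pass is a pure function of the raw recording:
        repeated application marks the same sample set."""
        rng = np.random.default_rng(4)
        vals = 3.0 + 0.01 * rng.normal(size=5000)
        vals[1200] = 8.5
        raw = np.ones(5000, bool)
        raw[3000:3100] = False
        params = CleaningParams()
        v1, _ = _validity_pass(vals, raw, RATE, params)
        v2, _ = _validity_pass(vals, raw, RATE, params)
        assert np.array_equal(v1, v2)

    def test_interpolation_bounded_by_flanking_values(self):
        """Linear interpolation never exceeds the flanking valid samples."""
        rng = np.random.default_rng(5)
        vals = 3.0 + 0.02 * rng.normal(size=5000)
        valid = np.ones(5000, bool)
        valid[1000:1090] = False
        left, right = pair(vals, valid)
        out, _ = clean_and_combine(left, right)
        lo, hi = vals.min(), vals.max()
        assert out.values[out.valid].min() >= lo - 1e-6
        assert out.values[out.valid].max() <= hi + 1e-6


class TestFixationExclusion:
    def _gaze(self, x, y, n=1000):
        return (
            SampledSeries(np.full(n, float(x)), RATE),
            SampledSeries(np.full(n, float(y)), RATE),
        )

    def test_central_fixation_keeps_everything(self):
        pupil = SampledSeries(np.full(1000, 3.0), RATE)
        gx, gy = self._gaze(0, 0)
        assert exclude_off_fixation(pupil, gx, gy).valid.all()

    def test_large_eccentricity_excludes_everything(self):
        pupil = SampledSeries(np.full(1000, 3.0), RATE)
        gx, gy = self._gaze(10, 0)
        assert not exclude_off_fixation(pupil, gx, gy).valid.any()

    def test_threshold_crossing_span_excluded_then_interpolated(self):
        n = 5000
        pupil_vals = np.full(n, 3.0)
        gx = np.zeros(n)
        gx[2000:2050] = 6.0  # 100 ms excursion beyond 4.74 degrees
        pupil = SampledSeries(pupil_vals, RATE)
        out = exclude_off_fixation(
            pupil, SampledSeries(gx, RATE), SampledSeries(np.zeros(n), RATE)
        )
        assert (~out.valid[2000:2050]).all()
        assert out.valid[:2000].all() and out.valid[2050:].all()
        cleaned, _ = clean_and_combine(out, out.copy())
        assert cleaned.valid.all()  # 100 ms < 250 ms: interpolated

    def test_missing_gaze_is_an_error(self):
        pupil = SampledSeries(np.full(10, 3.0), RATE)
        with pytest.raises(ValueError):
            exclude_off_fixation(pupil, None, None)

    def test_degrees_per_pixel_plausible(self):
        dpp = FixationParams().degrees_per_pixel((1280, 1024))
        assert 0.02 < dpp < 0.04


class TestNormalization:
    def test_constant_two_becomes_one(self):
        out = normalize_session(SampledSeries(np.full(100, 2.0), RATE))
        assert np.allclose(out.values, 1.0)

    def test_peak_is_exactly_one(self):
        rng = np.random.default_rng(0)
        vals = 3.0 + rng.uniform(0, 1, 500)
        out = normalize_session(SampledSeries(vals, RATE))
        assert out.values.max() == pytest.approx(1.0)

    def test_sessions_normalized_independently(self):
        a = normalize_session(SampledSeries(np.linspace(1, 2, 500), RATE))
        b = normalize_session(SampledSeries(np.linspace(2, 4, 500), RATE))
        assert a.values.max() == pytest.approx(1.0)
        assert b.values.max() == pytest.approx(1.0)

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            normalize_session(SampledSeries(np.full(10, -1.0), RATE))


class TestBaselineDiameter:
    def _events(self, labels, isi=2.0, start=2.0):
        return [(start + i * isi, lab) for i, lab in enumerate(labels)]

    def test_constant_trace(self):
        pupil = SampledSeries(np.full(10000, 2.89), RATE)
        events = self._events(["standard"] * 8)
        assert baseline_diameter(pupil, events) == pytest.approx(2.89)

    def test_post_oddball_trials_excluded(self):
        rate = RATE
        n = 10000
        vals = np.full(n, 2.8)
        labels = ["standard", "standard", "oddball", "standard", "standard"]
        events = self._events(labels)
        # poison the baseline window of the trial following the oddball
        t_poison = events[3][0]
        i0, i1 = int((t_poison - 0.5) * rate), int(t_poison * rate)
        vals[i0:i1] = 5.0
        pupil = SampledSeries(vals, rate)
        assert baseline_diameter(pupil, events) == pytest.approx(2.8)

    def test_no_eligible_trials_rejected(self):
        pupil = SampledSeries(np.full(100, 2.8), RATE)
        with pytest.raises(ValueError):
            baseline_diameter(pupil, [])


def test_extract_trials_drops_out_of_range_windows():
    s = SampledSeries(np.arange(5000.0), RATE, start=0.0)
    trials = extract_trials(s, [1.0, 9.0], 0.0, 4.0)
    assert len(trials) == 1
    assert len(trials[0]) == int(4.0 * RATE)
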