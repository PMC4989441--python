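"""Event detection, rate-series derivation and pulse transit time."""

import numpy as np
import pytest

from cardiostate.errors import NoEventsDetected, NoMatches, NonFiniteSignal, TooFewEvents
from cardiostate.events import (
    EventSeries,
    derive_rate_series,
    detect_breath_maxima,
    detect_pulse_feet,
    detect_r_peaks,
    pulse_transit_time,
)
from cardiostate.synthetic import _ecg_template


def _spike_train(times, fs, duration):
    x = np.zeros(int(fs * duration))
    tpl = _ecg_template(fs)
    half = tpl.size // 2
    for t in times:
        c = int(round(t * fs))
        x[c - half : c - half + tpl.size] += tpl
    return x


class TestRPeaks:
    def test_known_peak_times(self):
        fs = 100.0
        x = _spike_train([1.0, 2.0, 3.0], fs, 5.0)
        ev = detect_r_peaks(x, fs)
        np.testing.assert_allclose(ev.times, [1.0, 2.0, 3.0], atol=1.0 / fs)

    def test_flat_signal_raises(self):
        with pytest.raises(NoEventsDetected):
            detect_r_peaks(np.zeros(1000), 100.0)

    def test_single_beat(self):
        ev = detect_r_peaks(_spike_train([5.0], 100.0, 10.0), 100.0)
        assert len(ev) == 1
        assert abs(ev.times[0] - 5.0) <= 0.01

    def test_nonfinite_rejected(self):
        x = np.ones(500)
        x[10] = np.nan
        with pytest.raises(NonFiniteSignal):
            detect_r_peaks(x, 100.0)

    def test_counts_match_generator(self, awake_record):
        ev = detect_r_peaks(awake_record.channels["ecg"], awake_record.fs)
        assert len(ev) == awake_record.truth_events["r_peak"].size


class TestBreathMaxima:
    def test_pure_sinusoid_count_and_spacing(self):
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        ev = detect_breath_maxima(np.sin(2 * np.pi * 0.25 * t), fs)
        assert len(ev) == 15
        np.testing.assert_allclose(np.diff(ev.times), 4.0, atol=1.0 / fs)

    def test_noise_does_not_change_count(self):
        fs = 100.0
        t = np.arange(int(120 * fs)) / fs
        clean = np.sin(2 * np.pi * 0.25 * t)
        rng = np.random.default_rng(0)
        noisy = clean + 0.1 * rng.standard_normal(t.size)  # SNR 20 dB on power
        assert len(detect_breath_maxima(noisy, fs)) == len(detect_breath_maxima(clean, fs))

    def test_flat_raises(self):
        with pytest.raises(NoEventsDetected):
            detect_breath_maxima(np.full(2000, 3.7), 100.0)

    def test_counts_match_generator(self, awake_record):
        ev = detect_breath_maxima(awake_record.channels["resp"], awake_record.fs)
        truth = awake_record.truth_events["breath_max"]
        interior = truth[(truth > 1.0) & (truth < awake_record.duration - 1.0)]
        assert interior.size <= len(ev) <= truth.size


class TestPulseFeet:
    def test_minima_of_inverted_cosine(self):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        pulse = 1.0 - np.cos(2 * np.pi * 1.0 * t)  # feet at integer seconds
        ev = detect_pulse_feet(pulse, fs)
        expected = np.arange(1, 30)
        got = ev.times[(ev.times > 0.5) & (ev.times < 29.5)]
        np.testing.assert_allclose(got, expected, atol=1.0 / fs)

    def test_one_cycle_one_foot(self):
        fs = 100.0
        t = np.arange(int(2 * fs)) / fs
        ev = detect_pulse_feet(1.0 - np.cos(2 * np.pi * 0.75 * t + np.pi), fs)
        assert len(ev) == 1

    def test_flat_raises(self):
        with pytest.raises(NoEventsDetected):
            detect_pulse_feet(np.zeros(1000), 100.0)


class TestRateSeries:
    def test_constant_intervals_give_constant_rate(self):
        ev = EventSeries(times=np.arange(10, dtype=float), kind="r_peak")
        rs = derive_rate_series(ev, fs_out=10.0)
        np.testing.assert_allclose(rs.rate, 1.0, rtol=1e-9)
        assert rs.kind == "hrv"

    def test_alternating_intervals_hit_closed_form_at_midpoints(self):
        times = np.cumsum([0.0] + [0.9, 1.1] * 5)
        ev = EventSeries(times=times, kind="r_peak")
        rs = derive_rate_series(ev, fs_out=100.0)
        mid_fast = 0.5 * (times[0] + times[1])  # interval 0.9
        mid_slow = 0.5 * (times[1] + times[2])  # interval 1.1
        i_fast = np.argmin(np.abs(rs.t - mid_fast))
        i_slow = np.argmin(np.abs(rs.t - mid_slow))
        assert abs(rs.rate[i_fast] - 1 / 0.9) < 0.01
        assert abs(rs.rate[i_slow] - 1 / 1.1) < 0.01

    def test_mean_rate_matches_event_rate(self, awake_record):
        from cardiostate.events import detect_r_peaks

        ev = detect_r_peaks(awake_record.channels["ecg"], awake_record.fs)
        rs = derive_rate_series(ev, fs_out=10.0)
        event_rate = (len(ev) - 1) / (ev.times[-1] - ev.times[0])
        assert abs(rs.rate.mean() - event_rate) / event_rate < 0.02

    def test_scale_consistency_doubling_times_halves_rate(self):
        rng = np.random.default_rng(1)
        times = np.cumsum(rng.uniform(0.8, 1.2, 50))
        r1 = derive_rate_series(EventSeries(times=times, kind="r_peak"), fs_out=10.0)
        r2 = derive_rate_series(EventSeries(times=2 * times, kind="r_peak"), fs_out=10.0)
        assert abs(r2.rate.mean() - 0.5 * r1.rate.mean()) < 0.01 * r1.rate.mean()

    def test_too_few_events(self):
        with pytest.raises(TooFewEvents):
            derive_rate_series(EventSeries(times=np.array([0.0, 1.0]), kind="r_peak"))


class TestPulseTransitTime:
    def test_constant_shift_recovered(self):
        r = EventSeries(times=np.arange(1.0, 20.0), kind="r_peak")
        feet = EventSeries(times=r.times + 0.18, kind="pulse_foot")
        ptt = pulse_transit_time(r, feet)
        np.testing.assert_allclose(ptt.ptt, 0.18, atol=1e-12)

    @pytest.mark.parametrize("lag", [0.15, 0.18, 0.21])
    def test_generator_lag_recovered(self, lag):
        from dataclasses import replace

        from cardiostate.synthetic import awake_truth, generate_subject

        truth = replace(awake_truth(), ptt_lag=lag)
        rec = generate_subject(truth, fs=100.0, duration=300.0, seed=7)
        r = detect_r_peaks(rec.channels["ecg"], rec.fs)
        feet = detect_pulse_feet(rec.channels["pulse"], rec.fs)
        ptt = pulse_transit_time(r, feet)
        assert abs(ptt.mean - lag) <= 1.0 / rec.fs

    def test_missing_middle_foot_skipped(self):
        r = EventSeries(times=np.array([1.0, 2.0, 3.0]), kind="r_peak")
        feet = EventSeries(times=np.array([1.2, 3.2]), kind="pulse_foot")
        ptt = pulse_transit_time(r, feet)
        assert ptt.ptt.size == 2
        np.testing.assert_allclose(ptt.r_time, [1.0, 3.0])

    def test_feet_before_all_beats_raises(self):
        r = EventSeries(times=np.array([5.0, 6.0, 7.0]), kind="r_peak")
        feet = EventSeries(times=np.array([1.0, 2.0]), kind="pulse_foot")
        with pytest.raises(NoMatches):
            pulse_transit_time(r, feet)
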