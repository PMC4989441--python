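"""Phase extraction and m:n synchronisation index."""

import numpy as np
import pytest
from scipy.special import i0, i1

from cardiostate.errors import TooFewEvents, WindowTooShort
from cardiostate.events import EventSeries
from cardiostate.sync import PhasePair, event_phase, sync_index, sync_time, synchrogram


def _pair(phi_h, phi_r, fs=5.0):
    n = phi_h.size
    return PhasePair(t=np.arange(n) / fs, phi_heart=phi_h, phi_resp=phi_r)


def _uniform_pair(f_h, f_r, duration=600.0, fs=5.0):
    t = np.arange(int(duration * fs)) / fs
    return _pair(2 * np.pi * f_h * t, 2 * np.pi * f_r * t, fs)


class TestEventPhase:
    def test_closed_form_between_events(self):
        ev = EventSeries(times=np.array([0.0, 1.0, 2.0, 3.0]), kind="r_peak")
        phi = event_phase(ev, np.array([1.5]))
        assert phi[0] == pytest.approx(3 * np.pi)

    def test_exact_multiples_at_event_times(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(rng.uniform(0.5, 1.5, 30))
        ev = EventSeries(times=times, kind="r_peak")
        phi = event_phase(ev, times)
        np.testing.assert_allclose(phi, 2 * np.pi * np.arange(30), atol=1e-9)

    def test_non_decreasing_and_masked_outside(self):
        ev = EventSeries(times=np.array([1.0, 2.0, 4.0, 5.0]), kind="r_peak")
        grid = np.linspace(0, 6, 61)
        phi = event_phase(ev, grid)
        inside = np.isfinite(phi)
        assert np.all(np.diff(phi[inside]) >= 0)
        assert np.isnan(phi[grid < 1.0]).all() and np.isnan(phi[grid > 5.0]).all()

    def test_too_few_events(self):
        with pytest.raises(TooFewEvents):
            event_phase(EventSeries(times=np.array([0.0, 1.0]), kind="r_peak"), np.array([0.5]))


class TestSyncIndex:
    def test_exact_lock_gives_gamma_one(self):
        pair = _uniform_pair(1.0, 0.25)
        trace = sync_index(pair, 1, 4, window=24.0)
        np.testing.assert_allclose(trace.gamma, 1.0, atol=1e-9)

    def test_uniform_drift_through_full_cycle_gives_zero(self):
        # psi advances exactly one cycle per window -> circular mean ~ 0
        f_h, f_r = 1.0, 0.25
        window = 20.0
        delta = 1.0 / window  # Hz of psi drift
        pair = _uniform_pair(f_h + delta, f_r)
        trace = sync_index(pair, 1, 4, window=window)
        assert np.all(trace.gamma < 0.02)

    def test_von_mises_kappa2_matches_circular_mean(self):
        rng = np.random.default_rng(7)
        fs, duration = 5.0, 2000.0
        n = int(fs * duration)
        t = np.arange(n) / fs
        psi = rng.vonmises(0.5, 2.0, n)
        pair = _pair(2 * np.pi * 1.0 * t, 2 * np.pi * 0.25 * t + psi / 4.0, fs)
        trace = sync_index(pair, 1, 4, window=60.0)
        expected = i1(2.0) / i0(2.0)
        assert abs(trace.gamma.mean() - expected) < 0.02

    def test_invariance_under_joint_phase_offset(self):
        rng = np.random.default_rng(1)
        n = 3000
        t = np.arange(n) / 5.0
        wander = np.cumsum(0.01 * rng.standard_normal(n))
        pair1 = _pair(2 * np.pi * t + wander, 2 * np.pi * 0.25 * t)
        # add constant c to psi by shifting the heart phase
        pair2 = _pair(2 * np.pi * t + wander - 1.234, 2 * np.pi * 0.25 * t)
        g1 = sync_index(pair1, 1, 4, window=24.0).gamma
        g2 = sync_index(pair2, 1, 4, window=24.0).gamma
        np.testing.assert_allclose(g1, g2, atol=1e-9)

    def test_noise_monotonically_lowers_gamma(self):
        rng = np.random.default_rng(2)
        n = 6000
        t = np.arange(n) / 5.0
        base = 2 * np.pi * 1.0 * t
        means = []
        for sd in (0.1, 0.5, 1.5):
            noise = rng.vonmises(0, 1 / max(sd, 1e-9) ** 2, n) if False else sd * rng.standard_normal(n)
            pair = _pair(base + noise, 2 * np.pi * 0.25 * t)
            means.append(sync_index(pair, 1, 4, window=24.0).gamma.mean())
        assert means[0] > means[1] > means[2]

    def test_window_too_short_and_bad_ratio(self):
        pair = _uniform_pair(1.0, 0.25)
        with pytest.raises(WindowTooShort):
            sync_index(pair, 1, 4, window=5.0)
        with pytest.raises(ValueError):
            sync_index(pair, 0, 4, window=24.0)

    def test_entropy_variant_orders_like_circular(self):
        rng = np.random.default_rng(3)
        n = 6000
        t = np.arange(n) / 5.0
        locked = _pair(2 * np.pi * t + 0.05 * rng.standard_normal(n), 2 * np.pi * 0.25 * t)
        drifting = _uniform_pair(1.05, 0.25, duration=1200.0)
        g_lock = sync_index(locked, 1, 4, window=24.0, method="entropy").gamma.mean()
        g_drift = sync_index(drifting, 1, 4, window=24.0, method="entropy").gamma.mean()
        assert g_lock > g_drift


class TestSyncTime:
    def test_fully_locked_record_counts_almost_everything(self):
        pair = _uniform_pair(1.0, 0.25)
        res = sync_time(pair, T=4.0)
        span = pair.t[-1] - pair.t[0]
        assert abs(res.total_sync_time - (span - res.window_1n)) <= res.window_1n
        assert res.window_1n == pytest.approx(24.0)
        assert res.window_2n == pytest.approx(32.0)

    def test_union_not_double_counted(self):
        # 1:4 lock also satisfies 2:8; union must not exceed the span
        pair = _uniform_pair(1.0, 0.25)
        res = sync_time(pair, ratios=[(1, 4), (2, 8)], T=4.0)
        assert res.total_sync_time <= res.duration

    def test_drifting_phases_rarely_synchronised(self):
        rng = np.random.default_rng(5)
        fs, duration = 5.0, 600.0
        n = int(fs * duration)
        t = np.arange(n) / fs
        f_h = 0.25 * (4 + np.sqrt(2) / 2)  # irrational beats-per-breath
        wander = np.cumsum(0.03 * rng.standard_normal(n)) / fs
        pair = _pair(2 * np.pi * f_h * t + wander, 2 * np.pi * 0.25 * t)
        res = sync_time(pair, T=4.0)
        assert res.total_sync_time < 0.05 * res.duration

    def test_supremum_threshold_gives_zero_on_noisy_lock(self):
        rng = np.random.default_rng(6)
        n = 3000
        t = np.arange(n) / 5.0
        pair = _pair(2 * np.pi * t + 0.2 * rng.standard_normal(n), 2 * np.pi * 0.25 * t)
        res = sync_time(pair, ratios=[(1, 4)], T=4.0, threshold=1.0)
        assert res.total_sync_time == 0.0


def test_synchrogram_wraps_resp_phase_at_beats():
    beats = EventSeries(times=np.arange(1.0, 50.0), kind="r_peak")
    breaths = EventSeries(times=np.arange(0.5, 50.0, 4.0), kind="breath_max")
    t, phases = synchrogram(beats, breaths, m=1)
    assert np.all((phases >= 0) & (phases < 2 * np.pi))
    assert t.size > 0
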