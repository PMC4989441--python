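"""Marker-event detection and instantaneous-rate series.

R-peaks of the ECG and maxima of the respiration signal mark the cardiac
and respiratory oscillations; the feet (minima) of the integrated finger
pulse mark pressure-wave arrival.  From the marker times we build
heart-rate variability (HRV) and respiratory-frequency variability (RFV)
series — instantaneous rate 1/interval placed at interval midpoints and
linearly interpolated onto a uniform grid — and per-beat pulse transit
times (R-peak to corresponding pulse foot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .errors import NoEventsDetected, NoMatches, NonFiniteSignal, TooFewEvents

__all__ = [
    "EventSeries",
    "RateSeries",
    "PttSeries",
    "detect_r_peaks",
    "detect_breath_maxima",
    "detect_pulse_feet",
    "derive_rate_series",
    "pulse_transit_time",
]

CARDIAC_REFRACTORY = 0.25  # s
RESPIRATORY_REFRACTORY = 1.0  # s


def _parabolic_refine(y: np.ndarray, idx: np.ndarray, fs: float) -> np.ndarray:
    """Sub-sample extremum times by parabolic interpolation around each peak."""
    t = idx.astype(float)
    interior = (idx > 0) & (idx < y.size - 1)
    i = idx[interior]
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    shift = np.zeros(i.size)
    ok = np.abs(denom) > 1e-12
    shift[ok] = 0.5 * (y[i - 1] - y[i + 1])[ok] / denom[ok]
    t[interior] += np.clip(shift, -0.5, 0.5)
    return t / fs


@dataclass
class EventSeries:
    """Strictly increasing marker-event times of one kind."""

    times: np.ndarray  # s
    kind: str  # r_peak | breath_max | pulse_foot

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class RateSeries:
    """Instantaneous rate (Hz) on a uniform time grid."""

    t: np.ndarray  # s
    rate: np.ndarray  # Hz
    kind: str

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class PttSeries:
    """Per-beat pulse transit times: matched R-peak / pulse-foot pairs."""

    beat_index: np.ndarray
    r_time: np.ndarray
    foot_time: np.ndarray
    ptt: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.ptt.mean())


def _check_signal(x: np.ndarray, fs: float, min_duration: float = 2.0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise NonFiniteSignal("signal contains non-finite samples")
    if x.size < min_duration * fs:
        raise NoEventsDetected(f"need at least {min_duration} s of signal")
    return x


def _blockwise_threshold(det: np.ndarray, fs: float, block_s: float = 10.0, frac: float = 0.5) -> np.ndarray:
    """Adaptive height threshold: ``frac`` x blockwise 95th percentile, interpolated."""
    n = det.size
    block = max(int(block_s * fs), 1)
    starts = np.arange(0, n, block)
    centres = np.minimum(starts + block // 2, n - 1)
    p95 = np.array([np.percentile(det[s : s + block], 95) for s in starts])
    return np.interp(np.arange(n), centres, p95) * frac


def detect_r_peaks(ecg: np.ndarray, fs: float) -> EventSeries:
    """Detect ECG R-peaks.

    Band-pass 5-30 Hz (bypassed at fs <= 100 Hz where the band is most of
    the spectrum), squared derivative for QRS emphasis, adaptive threshold
    at half the blockwise 95th percentile, 0.25 s refractory; peak times
    are refined to the raw-signal maximum near each detection.
    """
    ecg = _check_signal(ecg, fs)
    x = ecg - np.median(ecg)
    if fs > 100:
        sos = sp_signal.butter(2, [5.0, 30.0], btype="bandpass", fs=fs, output="sos")
        x = sp_signal.sosfiltfilt(sos, x)
    det = np.gradient(x) ** 2
    if det.max() <= 0 or np.ptp(ecg) < 1e-12:
        raise NoEventsDetected("flat signal")
    height = _blockwise_threshold(det, fs)
    idx, _ = sp_signal.find_peaks(det, height=height, distance=max(int(CARDIAC_REFRACTORY * fs), 1))
    if idx.size == 0:
        raise NoEventsDetected("no R-peaks found")
    # refine to the raw-ECG local maximum (the R apex)
    half = max(int(0.05 * fs), 1)
    refined = []
    for i in idx:
        lo, hi = max(i - half, 0), min(i + half + 1, ecg.size)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    keep = [refined[0]]
    for i in refined[1:]:
        if i - keep[-1] >= CARDIAC_REFRACTORY * fs:
            keep.append(i)
    times = _parabolic_refine(ecg, np.asarray(keep), fs)
    return EventSeries(times=times, kind="r_peak")


def _detect_extrema(
    x: np.ndarray,
    fs: float,
    refractory: float,
    kind: str,
    minima: bool = False,
    lowpass: float | None = None,
) -> EventSeries:
    x = _check_signal(x, fs)
    if np.ptp(x) < 1e-12:
        raise NoEventsDetected("flat signal")
    y = -x if minima else x
    y = y - y.mean()
    if lowpass is not None and lowpass < 0.45 * fs:
        # noise on a flat extremum shifts its apparent location; smooth first
        sos = sp_signal.butter(4, lowpass, btype="low", fs=fs, output="sos")
        y = sp_signal.sosfiltfilt(sos, y)
    prominence = 0.25 * np.std(y)
    idx, _ = sp_signal.find_peaks(y, distance=max(int(refractory * fs), 1), prominence=prominence)
    if idx.size == 0:
        raise NoEventsDetected(f"no {kind} events found")
    return EventSeries(times=_parabolic_refine(y, idx, fs), kind=kind)


def detect_breath_maxima(resp: np.ndarray, fs: float) -> EventSeries:
    """Maxima of the respiratory-effort signal (1 s refractory).

    The signal is low-passed at 1.2 Hz first: respiratory effort is slow
    (< 0.6 Hz) and broadband noise otherwise dominates the flat peaks.
    """
    return _detect_extrema(resp, fs, RESPIRATORY_REFRACTORY, "breath_max", lowpass=1.2)


def detect_pulse_feet(pulse: np.ndarray, fs: float) -> EventSeries:
    """Per-beat minima of the integrated pulse signal (pressure-wave arrival)."""
    return _detect_extrema(pulse, fs, CARDIAC_REFRACTORY, "pulse_foot", minima=True)


def derive_rate_series(
    events: EventSeries,
    fs_out: float = 10.0,
    t_range: tuple[float, float] | None = None,
) -> RateSeries:
    """Instantaneous-rate variability series from marker events.

    Rate 1/interval is assigned at each interval midpoint, linearly
    interpolated onto a uniform grid of spacing ``1/fs_out``, and held
    constant beyond the first/last midpoint.
    """
    if len(events) < 3:
        raise TooFewEvents(f"need >= 3 events, got {len(events)}")
    times = events.times
    intervals = np.diff(times)
    midpoints = 0.5 * (times[:-1] + times[1:])
    rates = 1.0 / intervals
    if t_range is None:
        t_range = (float(times[0]), float(times[-1]))
    t = np.arange(t_range[0], t_range[1] + 0.5 / fs_out, 1.0 / fs_out)
    rate = np.interp(t, midpoints, rates)  # np.interp holds ends constant
    kind = {"r_peak": "hrv", "breath_max": "rfv"}.get(events.kind, events.kind)
    return RateSeries(t=t, rate=rate, kind=kind)


def pulse_transit_time(
    r_peaks: EventSeries, feet: EventSeries, max_lag: float = 0.6
) -> PttSeries:
    """Match each pulse foot to the latest preceding R-peak within ``max_lag``.

    Unmatched beats are skipped; each R-peak is used at most once.
    """
    if len(r_peaks) == 0 or len(feet) == 0:
        raise NoMatches("empty event series")
    r = r_peaks.times
    beat_idx, r_t, f_t = [], [], []
    used = -1
    for foot in feet.times:
        i = int(np.searchsorted(r, foot, side="right")) - 1
        if i < 0 or i == used:
            continue
        if foot - r[i] <= max_lag:
            beat_idx.append(i)
            r_t.append(r[i])
            f_t.append(foot)
            used = i
    if not beat_idx:
        raise NoMatches(f"no foot within {max_lag} s of a preceding R-peak")
    r_t = np.asarray(r_t)
    f_t = np.asarray(f_t)
    return PttSeries(
        beat_index=np.asarray(beat_idx), r_time=r_t, foot_time=f_t, ptt=f_t - r_t
    )
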