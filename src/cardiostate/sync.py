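"""Cardiorespiratory m:n phase synchronisation.

Marker events define a linearly interpolated phase that gains 2*pi per
event.  For a ratio m:n (m breathing cycles per n heartbeats) the
generalized phase difference is ``psi = n*phi_resp - m*phi_heart``, which
stays bounded under m:n locking.  The synchronisation index is the
circular mean ("mean phase coherence") of psi over a sliding window:
``gamma(t) = |<exp(i psi)>_window|``, equal to 1 exactly when psi is
constant in the window.  Total synchronisation time sums the intervals
where any examined ratio reaches 95% of perfect synchronisation, using
window lengths of 6T for 1:n and 8T for 2:n ratios, T being the mean
respiratory period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TooFewEvents, WindowTooShort
from .events import EventSeries

__all__ = ["PhasePair", "SyncTrace", "SyncResult", "event_phase", "sync_index", "sync_time", "synchrogram"]


def event_phase(events: EventSeries, t_grid: np.ndarray) -> np.ndarray:
    """Unwrapped phase from marker events, NaN outside the first/last event.

    ``phi(t) = 2*pi*(k + (t - t_k)/(t_{k+1} - t_k))`` for t in [t_k, t_{k+1}).
    """
    if len(events) < 3:
        raise TooFewEvents(f"need >= 3 events, got {len(events)}")
    times = events.times
    node_phase = 2 * np.pi * np.arange(times.size)
    phi = np.interp(t_grid, times, node_phase)
    phi[(t_grid < times[0]) | (t_grid > times[-1])] = np.nan
    return phi


@dataclass
class PhasePair:
    """Cardiac and respiratory phases on a shared uniform grid."""

    t: np.ndarray
    phi_heart: np.ndarray
    phi_resp: np.ndarray

    @classmethod
    def from_events(
        cls, r_peaks: EventSeries, breaths: EventSeries, fs_grid: float = 5.0
    ) -> "PhasePair":
        t0 = max(r_peaks.times[0], breaths.times[0])
        t1 = min(r_peaks.times[-1], breaths.times[-1])
        t = np.arange(t0, t1, 1.0 / fs_grid)
        return cls(t=t, phi_heart=event_phase(r_peaks, t), phi_resp=event_phase(breaths, t))

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def mean_rates(self) -> tuple[float, float]:
        """(heart, respiratory) mean rates in Hz from phase growth."""
        valid = np.isfinite(self.phi_heart) & np.isfinite(self.phi_resp)
        tv = self.t[valid]
        span = tv[-1] - tv[0]
        hr = (self.phi_heart[valid][-1] - self.phi_heart[valid][0]) / (2 * np.pi * span)
        rr = (self.phi_resp[valid][-1] - self.phi_resp[valid][0]) / (2 * np.pi * span)
        return float(hr), float(rr)

    def mean_resp_period(self) -> float:
        return 1.0 / self.mean_rates()[1]


@dataclass
class SyncTrace:
    """Windowed synchronisation index for one m:n ratio."""

    m: int
    n: int
    window: float  # s
    t: np.ndarray  # window centres, s
    gamma: np.ndarray  # index in [0, 1]


@dataclass
class SyncResult:
    """Synchronisation summary for one record."""

    traces: list[SyncTrace]
    T: float  # mean respiratory period, s
    window_1n: float  # 6T, s
    window_2n: float  # 8T, s
    total_sync_time: float  # s
    duration: float  # s
    threshold: float = 0.95


def _generalized_phase_diff(pair: PhasePair, m: int, n: int) -> np.ndarray:
    return n * pair.phi_resp - m * pair.phi_heart


def sync_index(
    pair: PhasePair,
    m: int,
    n: int,
    window: float,
    step: float = 1.0,
    method: str = "circular",
) -> SyncTrace:
    """Sliding-window synchronisation index gamma(t) for ratio m:n.

    ``method="circular"`` is the mean-phase-coherence form (gamma = 1 iff
    psi constant in the window); ``method="entropy"`` is the normalised
    Shannon-entropy variant 1 - S/S_max of the wrapped psi histogram.
    """
    if m <= 0 or n <= 0:
        raise ValueError("ratio m, n must be positive integers")
    T_est = pair.mean_resp_period()
    if window < 2 * T_est:
        raise WindowTooShort(f"window {window:.1f} s < 2T = {2 * T_est:.1f} s")
    psi = _generalized_phase_diff(pair, m, n)
    valid = np.isfinite(psi)
    fs = pair.fs
    w = max(int(round(window * fs)), 2)
    idx_valid = np.flatnonzero(valid)
    if idx_valid.size < w:
        raise WindowTooShort("record shorter than one window")
    i0, i1 = idx_valid[0], idx_valid[-1] + 1  # phases valid on a contiguous run
    psi_v = psi[i0:i1]

    step_samp = max(int(round(step * fs)), 1)
    centres = np.arange(i0 + w // 2, i1 - (w - w // 2) + 1, step_samp)
    if centres.size == 0:
        raise WindowTooShort("no full window fits inside the valid phase range")

    if method == "circular":
        c = np.cumsum(np.cos(psi_v))
        s = np.cumsum(np.sin(psi_v))
        starts = centres - i0 - w // 2
        ends = starts + w
        sum_c = c[ends - 1] - np.where(starts > 0, c[starts - 1], 0.0)
        sum_s = s[ends - 1] - np.where(starts > 0, s[starts - 1], 0.0)
        gamma = np.hypot(sum_c, sum_s) / w
    elif method == "entropy":
        n_bins = max(int(np.sqrt(w)), 4)
        wrapped = np.mod(psi_v, 2 * np.pi)
        gamma = np.empty(centres.size)
        for j, cidx in enumerate(centres - i0):
            seg = wrapped[cidx - w // 2 : cidx - w // 2 + w]
            p, _ = np.histogram(seg, bins=n_bins, range=(0, 2 * np.pi), density=False)
            p = p[p > 0] / seg.size
            gamma[j] = 1.0 + np.sum(p * np.log(p)) / np.log(n_bins)
    else:
        raise ValueError(f"unknown method {method!r}")
    np.clip(gamma, 0.0, 1.0, out=gamma)
    return SyncTrace(m=m, n=n, window=window, t=pair.t[centres], gamma=gamma)


def default_ratios(pair: PhasePair) -> list[tuple[int, int]]:
    """Candidate m:n ratios from the mean heart/respiratory rate ratio.

    1:n with n in round(HR/RR) +/- 2 and 2:n with odd n spanning the same
    range of beats-per-breath in half-integer steps.
    """
    hr, rr = pair.mean_rates()
    n0 = max(int(round(hr / rr)), 2)
    ratios = [(1, n) for n in range(max(n0 - 2, 2), n0 + 3)]
    for n in range(2 * n0 - 3, 2 * n0 + 4, 2):
        if n >= 3:
            ratios.append((2, n))
    return ratios


def sync_time(
    pair: PhasePair,
    ratios: list[tuple[int, int]] | None = None,
    T: float | None = None,
    threshold: float = 0.95,
    step: float = 1.0,
    method: str = "circular",
) -> SyncResult:
    """Total cardiorespiratory synchronisation time over candidate ratios.

    A time point counts as synchronised if any examined ratio's index
    reaches the threshold there; overlapping ratios are not double
    counted (the union of episodes is measured).
    """
    if ratios is None:
        ratios = default_ratios(pair)
    if T is None:
        T = pair.mean_resp_period()
    window_1n, window_2n = 6.0 * T, 8.0 * T

    traces: list[SyncTrace] = []
    union_t: np.ndarray | None = None
    union_mask: np.ndarray | None = None
    for m, n in ratios:
        window = window_1n if m == 1 else window_2n
        trace = sync_index(pair, m, n, window, step=step, method=method)
        traces.append(trace)
    # union over a common 1 s lattice spanning all trace centres
    t_lo = min(tr.t[0] for tr in traces)
    t_hi = max(tr.t[-1] for tr in traces)
    union_t = np.arange(t_lo, t_hi + step / 2, step)
    union_mask = np.zeros(union_t.size, dtype=bool)
    for tr in traces:
        hit = tr.gamma >= threshold
        idx = np.round((tr.t - t_lo) / step).astype(int)
        ok = (idx >= 0) & (idx < union_t.size)
        union_mask[idx[ok]] |= hit[ok]
    total = float(union_mask.sum() * step)
    duration = float(pair.t[-1] - pair.t[0])
    return SyncResult(
        traces=traces,
        T=float(T),
        window_1n=window_1n,
        window_2n=window_2n,
        total_sync_time=total,
        duration=duration,
        threshold=threshold,
    )


def synchrogram(r_peaks: EventSeries, breaths: EventSeries, m: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Stroboscopic synchrogram: respiratory phase (mod 2*pi*m) at R-peak times."""
    t = r_peaks.times
    phi_r = event_phase(breaths, t)
    keep = np.isfinite(phi_r)
    return t[keep], np.mod(phi_r[keep], 2 * np.pi * m)
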