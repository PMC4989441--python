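"""Morlet continuous wavelet transform and band-energy extraction.

The transform uses the analytic Morlet mother wavelet with centre
frequency ``omega0`` (default 6, the standard admissibility compromise).
Filtering is performed in the frequency domain by circular convolution;
record-edge wraparound artefacts are confined to the cone of influence
(COI), which every downstream average excludes.

Amplitude convention: the wavelet filter is normalised so that a
unit-amplitude sinusoid at a grid frequency produces coefficients of
modulus ~1 at that frequency, independent of sampling rate and record
length.  Band energy integrates ``|W(f,t)|^2 / f`` over log-frequency
(the 1/f weight is the established convention for cardiovascular wavelet
energy, equivalent to the 1/s^2 scale-domain weight), then averages over
the COI interior in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal

from .bands import BandScheme, DEFAULT_BANDS
from .errors import (
    DurationTooShort,
    EmptyCOI,
    EmptyInterval,
    NonFiniteSignal,
    NyquistViolation,
)

__all__ = ["WaveletTransform", "BandEnergyTable", "morlet_cwt", "band_energy"]

VOICES_PER_DECADE = 50


@dataclass
class WaveletTransform:
    """Complex time-frequency coefficients with cone-of-influence mask."""

    freqs: np.ndarray  # Hz, descending-free log-spaced grid (ascending here)
    times: np.ndarray  # s
    coeffs: np.ndarray  # complex, shape (n_freqs, n_times)
    coi_mask: np.ndarray  # bool, True = inside COI (edge-safe)
    fs: float
    omega0: float

    @property
    def dlogf(self) -> float:
        return float(np.log(self.freqs[1] / self.freqs[0]))

    def rolled(self, n_samples: int) -> "WaveletTransform":
        """Coefficients of the circularly time-shifted input signal.

        Because the transform is computed by circular convolution, rolling
        the coefficient matrix is exactly the transform of the rolled
        signal; the COI mask (a property of the grid, not the data) is
        unchanged.
        """
        return WaveletTransform(
            freqs=self.freqs,
            times=self.times,
            coeffs=np.roll(self.coeffs, n_samples, axis=1),
            coi_mask=self.coi_mask,
            fs=self.fs,
            omega0=self.omega0,
        )


@dataclass
class BandEnergyTable:
    """Time-averaged wavelet energy per frequency interval, (signal units)^2."""

    energies: dict[str, float]
    total: float
    kind: str = ""

    def __getitem__(self, interval: str) -> float:
        return self.energies[interval]


def _log_freq_grid(fmin: float, fmax: float, n_freqs: int | None) -> np.ndarray:
    if n_freqs is None:
        n_freqs = int(np.ceil(np.log10(fmax / fmin) * VOICES_PER_DECADE)) + 1
    return np.logspace(np.log10(fmin), np.log10(fmax), max(n_freqs, 2))


def morlet_cwt(
    x: np.ndarray,
    fs: float,
    fmin: float,
    fmax: float,
    n_freqs: int | None = None,
    omega0: float = 6.0,
    detrend: str = "mean",
) -> WaveletTransform:
    """Continuous wavelet transform of ``x`` on a log-spaced frequency grid.

    Parameters
    ----------
    x : array
        Uniformly sampled signal.
    fs : float
        Sampling rate, Hz.
    fmin, fmax : float
        Frequency range; ``fmax <= fs/2`` and ``fmin >= 2/duration`` (at
        least two oscillation periods must fit in the record).
    n_freqs : int, optional
        Number of grid frequencies; defaults to 50 voices per decade.
    omega0 : float
        Morlet centre frequency (dimensionless).
    detrend : {"mean", "linear", "none"}
        Pre-conditioning applied before the transform.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise NonFiniteSignal("signal contains non-finite samples")
    n = x.size
    duration = n / fs
    if fmax > fs / 2 + 1e-12:
        raise NyquistViolation(f"fmax={fmax} Hz exceeds fs/2={fs / 2} Hz")
    if fmin < 2.0 / duration - 1e-12:
        raise DurationTooShort(
            f"fmin={fmin} Hz needs >= {2.0 / fmin:.0f} s, record is {duration:.0f} s"
        )

    if detrend == "mean":
        x = x - x.mean()
    elif detrend == "linear":
        x = sp_signal.detrend(x, type="linear")

    freqs = _log_freq_grid(fmin, fmax, n_freqs)
    times = np.arange(n) / fs

    X = sp_fft.fft(x)
    omega = 2.0 * np.pi * sp_fft.fftfreq(n, d=1.0 / fs)
    pos = omega > 0

    coeffs = np.empty((freqs.size, n), dtype=complex)
    coi_mask = np.empty((freqs.size, n), dtype=bool)
    for i, f in enumerate(freqs):
        scale = omega0 / (2.0 * np.pi * f)  # seconds
        psi_hat = np.zeros(n)
        # analytic Morlet, gain calibrated so that a unit-amplitude sinusoid
        # contributes band energy A^2/2 (its variance) at any frequency
        gain = 2.0 * np.sqrt(f * omega0 / (2.0 * np.sqrt(np.pi)))
        psi_hat[pos] = gain * np.exp(-0.5 * (scale * omega[pos] - omega0) ** 2)
        coeffs[i] = sp_fft.ifft(X * psi_hat)
        efold = np.sqrt(2.0) * scale
        coi_mask[i] = (times >= efold) & (times <= duration - efold)

    return WaveletTransform(
        freqs=freqs, times=times, coeffs=coeffs, coi_mask=coi_mask, fs=fs, omega0=omega0
    )


def band_energy(wt: WaveletTransform, scheme: BandScheme = DEFAULT_BANDS, kind: str = "") -> BandEnergyTable:
    """Time-averaged energy per physiological frequency interval.

    Each grid frequency is assigned to exactly one interval of the scheme
    (intervals partition the analysed range), so interval energies are
    additive: their sum equals the total over the grid.  Only samples
    inside the cone of influence enter the time average.
    """
    if not wt.coi_mask.any():
        raise EmptyCOI("no sample lies inside the cone of influence")
    dlogf = wt.dlogf
    power = np.abs(wt.coeffs) ** 2

    # time-average each frequency row over its own COI interior
    row_mean = np.zeros(wt.freqs.size)
    for i in range(wt.freqs.size):
        valid = wt.coi_mask[i]
        if valid.any():
            row_mean[i] = power[i, valid].mean()
    density = row_mean / wt.freqs * dlogf

    energies: dict[str, float] = {}
    grid_lo, grid_hi = wt.freqs[0], wt.freqs[-1]
    for name, (lo, hi) in scheme.intervals.items():
        if hi <= grid_lo or lo >= grid_hi:
            continue  # interval entirely outside the analysed range
        in_band = np.array([scheme.locate(f) == name for f in wt.freqs])
        if not in_band.any():
            raise EmptyInterval(f"interval {name} contains no grid frequency")
        energies[name] = float(density[in_band].sum())
    total = float(sum(energies.values()))
    return BandEnergyTable(energies=energies, total=total, kind=kind)
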