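"""Synthetic multichannel cardiovascular recordings with known ground truth.

Emulates a two-state (awake / anaesthetised), two-agent (sevoflurane /
propofol) cohort of six-channel recordings: ECG, respiratory effort, skin
conductivity, two skin temperatures and finger pulse.  Each record is
driven by coupled phase oscillators — an integrate-and-fire cardiac phase
whose instantaneous rate carries respiratory sinus arrhythmia (RSA),
band-limited low-frequency modulations and slow Ornstein-Uhlenbeck
frequency wander — so that every downstream quantity (event times, rate
variability, band energies, coherence, m:n synchronisation, pulse transit
time) has a known generating value.

Default state parameters follow the reported clinical cohort means:
mean heart rate 1.07 Hz, respiratory rate 0.22 Hz awake rising to
0.37 Hz under sevoflurane, skin temperature ~30 degC rising ~2 degC under
anaesthesia, skin conductivity falling, pulse transit time 0.18 s rising
17% (sevoflurane) / 11% (propofol), heart-rate and respiratory-frequency
variability energies falling, and cardiorespiratory synchronisation time
roughly doubling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import DEFAULT_BANDS

__all__ = [
    "OscillatorSpec",
    "SubjectTruth",
    "SignalRecord",
    "SubjectPair",
    "generate_subject",
    "generate_cohort",
    "awake_truth",
    "anaesthetised_truth",
]

CHANNELS = ("ecg", "resp", "scond", "temp_wrist", "temp_ankle", "pulse")

# geometric-mean centre frequencies of intervals II..VI (Hz)
_BAND_CENTRE = {name: DEFAULT_BANDS.centre(name) for name in DEFAULT_BANDS.names}


@dataclass(frozen=True)
class OscillatorSpec:
    """One oscillatory component: centre frequency, jitter, amplitude, phase."""

    centre_frequency: float  # Hz
    frequency_jitter_sd: float = 0.0  # Hz
    amplitude: float = 1.0  # signal units
    phase0: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.centre_frequency <= 0:
            raise ValueError("centre_frequency must be > 0")
        if self.amplitude < 0 or self.frequency_jitter_sd < 0:
            raise ValueError("amplitude and jitter_sd must be >= 0")


@dataclass
class SubjectTruth:
    """Ground-truth generating parameters for one subject-state record."""

    mean_heart_rate: float = 1.07  # Hz
    mean_resp_rate: float = 0.22  # Hz
    ptt_lag: float = 0.18  # s
    rsa_coupling_strength: float = 0.05  # Hz (RSA modulation depth of HR)
    sync_ratio: tuple[int, int] | None = None  # (m breaths : n beats)
    sync_fraction: float = 0.0  # fraction of record spent phase-locked
    # per-channel-kind band modulation amplitudes keyed by interval I..VI
    modulations: dict[str, dict[str, float]] = field(default_factory=dict)
    # common low-frequency (myogenic, ~0.1 Hz) drive couplings per channel
    common_drive_coupling: dict[str, float] = field(default_factory=dict)
    mean_temperature: float = 30.0  # degC
    mean_conductivity: float = 2.0  # microsiemens
    burst_rate: float = 2.0 / 60.0  # conductivity bursts per second
    cardiac_in_temperature: float = 0.015  # degC, for pulse-temperature coherence I
    hr_jitter_sd: float = 0.02  # Hz, OU wander of cardiac rate
    rr_jitter_sd: float = 0.01  # Hz, OU wander of respiratory rate
    state: str = "awake"

    def __post_init__(self) -> None:
        if self.mean_heart_rate <= 0 or self.mean_resp_rate <= 0:
            raise ValueError("rates must be positive")
        if self.ptt_lag < 0:
            raise ValueError("ptt_lag must be >= 0")
        if self.sync_ratio is not None:
            m, n = self.sync_ratio
            if not (int(m) == m and int(n) == n and m >= 1 and n >= 1):
                raise ValueError("sync_ratio must be a pair of integers >= 1")
        if not 0.0 <= self.sync_fraction <= 1.0:
            raise ValueError("sync_fraction must lie in [0, 1]")


@dataclass
class SignalRecord:
    """One subject-state multichannel uniformly sampled recording."""

    channels: dict[str, np.ndarray]
    fs: float
    duration: float
    subject_id: str = ""
    state: str = "awake"
    truth: SubjectTruth | None = None
    # ground-truth event times (s) for recovery tests, keyed r_peak/breath_max
    truth_events: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = int(round(self.fs * self.duration))
        for name, x in self.channels.items():
            if x.size != n:
                raise ValueError(f"channel {name}: length {x.size} != fs*duration {n}")


@dataclass
class SubjectPair:
    """Paired awake / anaesthetised records of one subject."""

    subject_id: str
    agent: str  # sevoflurane | propofol
    awake: SignalRecord
    anaes: SignalRecord


def _ou(rng: np.random.Generator, n: int, dt: float, tau: float, sd: float) -> np.ndarray:
    """Ornstein-Uhlenbeck process: stationary sd ``sd``, correlation time ``tau``."""
    if sd == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    noise = rng.standard_normal(n) * sd * np.sqrt(1 - a * a)
    noise[0] = rng.standard_normal() * sd  # stationary start
    return lfilter([1.0], [1.0, -a], noise)


def _band_modulation(
    rng: np.random.Generator, t: np.ndarray, mods: dict[str, float]
) -> np.ndarray:
    """Sum of sinusoids at the interval centre frequencies (phase randomised)."""
    out = np.zeros_like(t)
    for interval, amp in mods.items():
        if amp == 0:
            continue
        f = _BAND_CENTRE[interval] * rng.uniform(0.92, 1.08)
        out += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def _phase_crossings(phase: np.ndarray, t: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Times where an unwrapped non-decreasing phase crosses offset + 2*pi*k."""
    k0 = int(np.ceil((phase[0] - offset) / (2 * np.pi)))
    k1 = int(np.floor((phase[-1] - offset) / (2 * np.pi)))
    if k1 < k0:
        return np.array([])
    targets = offset + 2 * np.pi * np.arange(k0, k1 + 1)
    return np.interp(targets, phase, t)


def _ecg_template(fs: float) -> np.ndarray:
    """Fixed Gaussian-difference beat template (R spike minus broad trough)."""
    sig_r = 0.014  # s
    tt = np.arange(-0.12, 0.12 + 1e-9, 1.0 / fs)
    return np.exp(-0.5 * (tt / sig_r) ** 2) - 0.25 * np.exp(-0.5 * (tt / (4 * sig_r)) ** 2)


def _add_events(signal: np.ndarray, times: np.ndarray, template: np.ndarray, fs: float) -> None:
    half = template.size // 2
    n = signal.size
    for tc in times:
        c = int(round(tc * fs))
        lo, hi = c - half, c - half + template.size
        s0, s1 = max(lo, 0), min(hi, n)
        signal[s0:s1] += template[s0 - lo : template.size - (hi - s1)]


def generate_subject(
    truth: SubjectTruth, fs: float = 100.0, duration: float = 600.0, seed: int = 0
) -> SignalRecord:
    """Simulate one six-channel recording from ground-truth parameters.

    The cardiac phase integrates ``dphi_h/dt = 2*pi*(f_hr + RSA*sin(phi_r)
    + band modulations + common drive + OU jitter)``; inside phase-locked
    episodes it instead tracks ``(n/m)*dphi_r`` with a weak restoring term
    so the generalized phase difference ``n*phi_r - m*phi_h`` stays
    bounded (exactly constant when all jitter is zero).
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    if fs <= 2.0 * truth.mean_heart_rate:
        raise ValueError(f"fs={fs} violates Nyquist for cardiac rate {truth.mean_heart_rate} Hz")

    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    dt = 1.0 / fs
    t = np.arange(n) * dt
    mods = truth.modulations
    drive_k = truth.common_drive_coupling

    # ---- common low-frequency drive (myogenic band, ~0.1 Hz) ----
    f_drive = 0.1 + _ou(rng, n, dt, tau=50.0, sd=0.008)
    phi_drive = 2 * np.pi * np.cumsum(f_drive) * dt + rng.uniform(0, 2 * np.pi)
    drive = np.sin(phi_drive)

    # ---- respiratory phase ----
    f_r = (
        truth.mean_resp_rate
        + _ou(rng, n, dt, tau=60.0, sd=truth.rr_jitter_sd)
        + _band_modulation(rng, t, mods.get("rfv", {}))
    )
    np.clip(f_r, 0.05 * truth.mean_resp_rate, None, out=f_r)
    phi_r = 2 * np.pi * np.cumsum(f_r) * dt + rng.uniform(0, 2 * np.pi)

    # ---- cardiac phase ----
    f_h_free = (
        truth.mean_heart_rate
        + truth.rsa_coupling_strength * np.sin(phi_r)
        + _band_modulation(rng, t, mods.get("hrv", {}))
        + drive_k.get("hrv", 0.0) * drive
        + _ou(rng, n, dt, tau=40.0, sd=truth.hr_jitter_sd)
    )
    np.clip(f_h_free, 0.2 * truth.mean_heart_rate, None, out=f_h_free)

    if truth.sync_ratio is not None and truth.sync_fraction > 0:
        m, nr = truth.sync_ratio
        locked = _locked_mask(rng, n, dt, duration, truth.sync_fraction)
        phi_h = np.empty(n)
        phi_h[0] = phi_r[0] * nr / m
        kappa = 1.0  # rad/s restoring rate inside locked episodes
        dphi_r = np.diff(phi_r, prepend=phi_r[0] - 2 * np.pi * f_r[0] * dt)
        for k in range(1, n):
            if locked[k]:
                psi = nr * phi_r[k - 1] - m * phi_h[k - 1]
                dphi = (nr / m) * dphi_r[k] + (kappa / m) * np.sin(psi) * dt
            else:
                dphi = 2 * np.pi * f_h_free[k] * dt
            phi_h[k] = phi_h[k - 1] + dphi
    else:
        phi_h = 2 * np.pi * np.cumsum(f_h_free) * dt
        phi_h += rng.uniform(0, 2 * np.pi)

    beat_times = _phase_crossings(phi_h, t)
    breath_times = _phase_crossings(phi_r, t, offset=np.pi / 2)  # maxima of sin

    # ---- channels ----
    ecg = np.zeros(n)
    _add_events(ecg, beat_times, _ecg_template(fs), fs)
    ecg += 0.01 * rng.standard_normal(n)

    resp = np.sin(phi_r) + 0.02 * rng.standard_normal(n)

    lag_samp = int(round(truth.ptt_lag * fs))
    phi_pulse = np.concatenate([np.full(lag_samp, phi_h[0]), phi_h[: n - lag_samp]]) if lag_samp else phi_h
    pulse = (1.0 - np.cos(phi_pulse)) * (1.0 + 0.05 * drive_k.get("pulse", 0.0) * drive)
    pulse += drive_k.get("pulse", 0.0) * drive + 0.01 * rng.standard_normal(n)

    scond = np.full(n, truth.mean_conductivity, dtype=float)
    scond += _band_modulation(rng, t, mods.get("scond", {}))
    scond += drive_k.get("scond", 0.0) * drive
    scond += truth.mean_conductivity * 0.02 * _ou(rng, n, dt, tau=200.0, sd=1.0)
    scond += _conductivity_bursts(rng, t, truth.burst_rate, 0.2 * truth.mean_conductivity)
    scond += 0.005 * rng.standard_normal(n)

    temp_osc = _band_modulation(rng, t, mods.get("temp", {}))
    cardiac_ripple = truth.cardiac_in_temperature * np.sin(phi_pulse)
    temp_common = drive_k.get("temp", 0.0) * drive
    temp_wrist = truth.mean_temperature + temp_osc + temp_common + cardiac_ripple
    temp_wrist += 0.005 * rng.standard_normal(n)
    temp_ankle = truth.mean_temperature - 0.8 + 0.8 * temp_osc + temp_common + cardiac_ripple
    temp_ankle += 0.005 * rng.standard_normal(n)

    return SignalRecord(
        channels={
            "ecg": ecg,
            "resp": resp,
            "scond": scond,
            "temp_wrist": temp_wrist,
            "temp_ankle": temp_ankle,
            "pulse": pulse,
        },
        fs=fs,
        duration=duration,
        state=truth.state,
        truth=truth,
        truth_events={"r_peak": beat_times, "breath_max": breath_times},
    )


def _locked_mask(
    rng: np.random.Generator, n: int, dt: float, duration: float, fraction: float
) -> np.ndarray:
    """Boolean mask of phase-locked samples: evenly spaced episodes."""
    if fraction >= 0.999:
        return np.ones(n, dtype=bool)
    n_ep = max(1, int(round(fraction * duration / 90.0)))
    ep_len = fraction * duration / n_ep
    mask = np.zeros(n, dtype=bool)
    block = duration / n_ep
    for j in range(n_ep):
        start = j * block + rng.uniform(0, max(block - ep_len, 0))
        i0, i1 = int(start / dt), int((start + ep_len) / dt)
        mask[i0:min(i1, n)] = True
    return mask


def _conductivity_bursts(
    rng: np.random.Generator, t: np.ndarray, rate: float, amplitude: float
) -> np.ndarray:
    """Poisson-timed exponential sweat-burst transients (fast rise, slow decay)."""
    out = np.zeros_like(t)
    if rate <= 0 or amplitude <= 0:
        return out
    n_bursts = rng.poisson(rate * t[-1]) if t.size else 0
    starts = np.sort(rng.uniform(0, t[-1], n_bursts))
    for t0 in starts:
        amp = amplitude * rng.uniform(0.5, 1.5)
        tail = t >= t0
        dt_tail = t[tail] - t0
        out[tail] += amp * (1 - np.exp(-dt_tail / 0.5)) * np.exp(-dt_tail / 5.0)
    return out


# ---------------------------------------------------------------------------
# default state parameterisations (clinical-cohort configuration targets)
# ---------------------------------------------------------------------------

_AWAKE_MODS = {
    "hrv": {"III": 0.090, "IV": 0.066, "V": 0.050, "VI": 0.036},
    "rfv": {"III": 0.012, "IV": 0.010, "V": 0.008},
    "scond": {"III": 0.04, "IV": 0.05, "V": 0.05, "VI": 0.05},
    "temp": {"IV": 0.05, "V": 0.07, "VI": 0.08},
}
_AWAKE_DRIVE = {"hrv": 0.03, "scond": 0.16, "pulse": 0.12, "temp": 0.05}


def awake_truth() -> SubjectTruth:
    """Default awake-state generating parameters."""
    return SubjectTruth(
        mean_heart_rate=1.07,
        mean_resp_rate=0.22,
        ptt_lag=0.18,
        rsa_coupling_strength=0.08,
        sync_ratio=(1, 5),
        sync_fraction=0.10,
        modulations={k: dict(v) for k, v in _AWAKE_MODS.items()},
        common_drive_coupling=dict(_AWAKE_DRIVE),
        mean_temperature=30.0,
        mean_conductivity=2.0,
        burst_rate=2.0 / 60.0,
        cardiac_in_temperature=0.02,
        state="awake",
    )


def anaesthetised_truth(agent: str) -> SubjectTruth:
    """Default anaesthetised-state parameters for one agent.

    Sevoflurane: respiratory rate up (~0.22 -> 0.37 Hz), PTT up 17%, HRV and
    RFV modulation depths down across all bands.  Propofol: slight HR and RR
    rise, PTT up 11%, HRV reduced mainly in the slowest bands (V, VI).  Both:
    skin temperature up ~2 degC, conductivity level/variability and coherent
    common drive down, synchronised fraction roughly doubled, sweat-burst
    rate halved.
    """
    base = awake_truth()
    anaes_drive = {"hrv": 0.004, "scond": 0.015, "pulse": 0.012, "temp": 0.005}
    if agent == "sevoflurane":
        mods = {
            "hrv": {b: a * 0.35 for b, a in _AWAKE_MODS["hrv"].items()},
            "rfv": {b: a * 0.60 for b, a in _AWAKE_MODS["rfv"].items()},
            "scond": {b: a * 0.06 for b, a in _AWAKE_MODS["scond"].items()},
            "temp": dict(_AWAKE_MODS["temp"]),
        }
        return replace(
            base,
            mean_resp_rate=0.37,
            ptt_lag=0.18 * 1.17,
            rsa_coupling_strength=0.03,
            sync_fraction=0.22,
            modulations=mods,
            common_drive_coupling=anaes_drive,
            mean_temperature=32.1,
            mean_conductivity=1.34,
            burst_rate=1.0 / 60.0,
            cardiac_in_temperature=0.005,
            state="sevoflurane",
        )
    if agent == "propofol":
        mods = {
            "hrv": {"III": 0.095, "IV": 0.070, "V": 0.018, "VI": 0.012},
            "rfv": {b: a * 0.75 for b, a in _AWAKE_MODS["rfv"].items()},
            "scond": {b: a * 0.06 for b, a in _AWAKE_MODS["scond"].items()},
            "temp": dict(_AWAKE_MODS["temp"]),
        }
        return replace(
            base,
            mean_heart_rate=1.14,
            mean_resp_rate=0.23,
            ptt_lag=0.18 * 1.11,
            rsa_coupling_strength=0.04,
            sync_fraction=0.22,
            modulations=mods,
            common_drive_coupling=anaes_drive,
            mean_temperature=31.9,
            mean_conductivity=1.67,
            burst_rate=1.0 / 60.0,
            cardiac_in_temperature=0.005,
            state="propofol",
        )
    raise ValueError(f"unknown agent {agent!r}")


# between-subject SDs applied around the state means (clinical-cohort spread)
_SUBJECT_SD = {
    "mean_heart_rate": 0.16,
    "mean_resp_rate": 0.05,
    "mean_temperature": 0.9,
    "ptt_lag": 0.02,
}


def _draw_subject_truths(
    rng: np.random.Generator,
    agent: str,
    awake_base: SubjectTruth,
    anaes_base: SubjectTruth,
) -> tuple[SubjectTruth, SubjectTruth]:
    """One subject's paired truths: correlated awake/anaesthetised draws."""
    hr = max(0.6, awake_base.mean_heart_rate + rng.normal(0, _SUBJECT_SD["mean_heart_rate"]))
    rr = max(0.10, awake_base.mean_resp_rate + rng.normal(0, _SUBJECT_SD["mean_resp_rate"]))
    temp = awake_base.mean_temperature + rng.normal(0, _SUBJECT_SD["mean_temperature"])
    ptt = max(0.08, awake_base.ptt_lag + rng.normal(0, _SUBJECT_SD["ptt_lag"]))
    cond = awake_base.mean_conductivity * rng.lognormal(0, 0.6)
    n_awake = max(2, int(round(hr / rr)))
    awake = replace(
        awake_base,
        mean_heart_rate=hr,
        mean_resp_rate=rr,
        mean_temperature=temp,
        ptt_lag=ptt,
        mean_conductivity=cond,
        sync_ratio=(1, n_awake),
        sync_fraction=rng.uniform(0.05, 0.15),
    )
    hr_a = hr + (anaes_base.mean_heart_rate - awake_base.mean_heart_rate) + rng.normal(0, 0.04)
    rr_a = max(0.10, rr + (anaes_base.mean_resp_rate - awake_base.mean_resp_rate) + rng.normal(0, 0.03))
    ptt_ratio = anaes_base.ptt_lag / awake_base.ptt_lag
    n_anaes = max(2, int(round(hr_a / rr_a)))
    anaes = replace(
        anaes_base,
        mean_heart_rate=max(0.6, hr_a),
        mean_resp_rate=rr_a,
        mean_temperature=temp + (anaes_base.mean_temperature - awake_base.mean_temperature) + rng.normal(0, 0.4),
        ptt_lag=ptt * ptt_ratio * rng.normal(1.0, 0.02),
        mean_conductivity=cond * (anaes_base.mean_conductivity / awake_base.mean_conductivity) * rng.lognormal(0, 0.15),
        sync_ratio=(1, n_anaes),
        sync_fraction=rng.uniform(0.15, 0.30),
    )
    return awake, anaes


def generate_cohort(
    n_sevo: int = 15,
    n_prop: int = 12,
    awake_params: SubjectTruth | None = None,
    anaes_params: dict[str, SubjectTruth] | None = None,
    fs: float = 100.0,
    duration: float = 600.0,
    seed: int = 0,
) -> list[SubjectPair]:
    """Generate a paired awake/anaesthetised cohort (default 15 sevo + 12 prop)."""
    if n_sevo < 0 or n_prop < 0 or n_sevo + n_prop == 0:
        raise ValueError("need at least one subject")
    awake_base = awake_params if awake_params is not None else awake_truth()
    if anaes_params is None:
        anaes_params = {
            "sevoflurane": anaesthetised_truth("sevoflurane"),
            "propofol": anaesthetised_truth("propofol"),
        }
    for agent in ["sevoflurane"] * min(n_sevo, 1) + ["propofol"] * min(n_prop, 1):
        if agent not in anaes_params:
            raise ValueError(f"anaes_params missing agent {agent!r}")

    ss = np.random.SeedSequence(seed)
    pairs: list[SubjectPair] = []
    agents = ["sevoflurane"] * n_sevo + ["propofol"] * n_prop
    child_seeds = ss.generate_state(3 * len(agents), dtype=np.uint32)
    for i, agent in enumerate(agents):
        rng = np.random.default_rng(int(child_seeds[3 * i]))
        truth_aw, truth_an = _draw_subject_truths(rng, agent, awake_base, anaes_params[agent])
        sid = f"{'S' if agent == 'sevoflurane' else 'P'}{i:02d}"
        rec_aw = generate_subject(truth_aw, fs, duration, int(child_seeds[3 * i + 1]))
        rec_an = generate_subject(truth_an, fs, duration, int(child_seeds[3 * i + 2]))
        rec_aw.subject_id = rec_an.subject_id = sid
        pairs.append(SubjectPair(subject_id=sid, agent=agent, awake=rec_aw, anaes=rec_an))
    return pairs
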