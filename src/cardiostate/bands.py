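"""Physiological frequency intervals for cardiovascular oscillations.

The cardiovascular system exhibits at least five characteristic oscillatory
processes, each attributed to a physiological origin: the heartbeat itself
(interval I), respiration (II), intrinsic myogenic activity of vascular
smooth muscle (III), neurogenic/sympathetic activity (IV) and NO-dependent
endothelial activity (V).  Interval VI is a contiguous extension below V
used by the conductivity/temperature variability attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BandScheme", "DEFAULT_BANDS", "PHYSIOLOGICAL_ORIGIN"]

PHYSIOLOGICAL_ORIGIN = {
    "I": "heartbeat",
    "II": "respiratory activity",
    "III": "intrinsic myogenic activity",
    "IV": "neurogenic (sympathetic) activity",
    "V": "NO-dependent endothelial activity",
    "VI": "slow endothelial/metabolic extension",
}


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous, non-overlapping frequency intervals (Hz).

    Keys are Roman numerals ordered from the fastest (I) to the slowest
    (VI) interval; each value is an ``(f_lo, f_hi)`` pair with
    ``f_lo < f_hi`` and adjacent intervals sharing a bound.
    """

    intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "I": (0.6, 2.0),
            "II": (0.145, 0.6),
            "III": (0.052, 0.145),
            "IV": (0.021, 0.052),
            "V": (0.0095, 0.021),
            "VI": (0.005, 0.0095),
        }
    )

    def __post_init__(self) -> None:
        prev_lo = np.inf
        for name, (lo, hi) in self.intervals.items():
            if not 0 < lo < hi:
                raise ValueError(f"interval {name}: need 0 < lo < hi, got {(lo, hi)}")
            if lo >= prev_lo:
                raise ValueError("interval lower bounds must strictly decrease")
            prev_lo = lo

    @property
    def names(self) -> list[str]:
        return list(self.intervals)

    @property
    def fmin(self) -> float:
        return min(lo for lo, _ in self.intervals.values())

    @property
    def fmax(self) -> float:
        return max(hi for _, hi in self.intervals.values())

    def centre(self, name: str) -> float:
        """Geometric-mean centre frequency of an interval (Hz)."""
        lo, hi = self.intervals[name]
        return float(np.sqrt(lo * hi))

    def locate(self, freq: float) -> str | None:
        """Name of the interval containing ``freq``, or None."""
        for name, (lo, hi) in self.intervals.items():
            if lo <= freq < hi or (freq == hi == self.fmax):
                return name
        return None

    def restricted(self, names: list[str]) -> "BandScheme":
        return BandScheme({n: self.intervals[n] for n in names})


DEFAULT_BANDS = BandScheme()
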