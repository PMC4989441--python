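"""Independent brute-force oracles used by the test suite.

These enumerate null distributions directly (all sign patterns / group
assignments) and never call the library code they are used to check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def wilcoxon_exact_p(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumeration of all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = 2**n
    stats = np.zeros(total)
    for mask in range(total):
        signs = np.array([(mask >> k) & 1 for k in range(n)], dtype=bool)
        stats[mask] = ranks[signs].sum()
    p_le = np.mean(stats <= w_obs)
    p_ge = np.mean(stats >= w_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def ranksum_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of all group assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = a.size
    r_obs = ranks[:na].sum()
    stats = [ranks[list(idx)].sum() for idx in combinations(range(pooled.size), na)]
    stats = np.asarray(stats)
    p_le = np.mean(stats <= r_obs)
    p_ge = np.mean(stats >= r_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def ks_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Permutation-exact two-sample KS p: P(D_perm >= D_obs)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    def ks_stat(x: np.ndarray, y: np.ndarray) -> float:
        grid = np.sort(np.concatenate([x, y]))
        cdf_x = np.searchsorted(np.sort(x), grid, side="right") / x.size
        cdf_y = np.searchsorted(np.sort(y), grid, side="right") / y.size
        return float(np.max(np.abs(cdf_x - cdf_y)))

    d_obs = ks_stat(a, b)
    pooled = np.concatenate([a, b])
    na = pooled.size - b.size
    count = 0
    total = 0
    for idx in combinations(range(pooled.size), na):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(idx)] = True
        total += 1
        if ks_stat(pooled[sel], pooled[~sel]) >= d_obs - 1e-12:
            count += 1
    return count / total


def periodogram_band_fraction(
    x: np.ndarray, fs: float, lo: float, hi: float
) -> float:
    """Fraction of detrended signal variance in [lo, hi) Hz via the DFT."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    total = spec[1:].sum()
    sel = (freqs >= lo) & (freqs < hi)
    return float(spec[sel].sum() / total) if total > 0 else 0.0
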