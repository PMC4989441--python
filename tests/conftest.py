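"""Shared fixtures: small synthetic records with known ground truth."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from cardiostate.synthetic import awake_truth, generate_subject


@pytest.fixture(scope="session")
def awake_record():
    """300 s default-awake record at 100 Hz, seed fixed."""
    return generate_subject(awake_truth(), fs=100.0, duration=300.0, seed=101)


@pytest.fixture(scope="session")
def locked_record():
    """Fully 1:4 phase-locked record with all jitter removed."""
    truth = replace(
        awake_truth(),
        sync_ratio=(1, 4),
        sync_fraction=1.0,
        hr_jitter_sd=0.0,
        rr_jitter_sd=0.0,
        rsa_coupling_strength=0.0,
        modulations={},
        common_drive_coupling={},
        mean_resp_rate=0.25,
        mean_heart_rate=1.0,
    )
    return generate_subject(truth, fs=100.0, duration=600.0, seed=202)


def make_feature_problem(
    n_per_class: int = 8,
    n_attrs: int = 4,
    informative: int | str = 0,
    gap: float = 12.0,
    noise: float = 0.5,
    seed: int = 0,
):
    """Three-class feature table with a controllable class gap.

    ``informative`` selects which attribute carries the class signal; the
    rest are pure noise (which per-attribute z-scoring inflates to unit
    variance, so single-attribute problems are never trivially separable).
    ``informative="all"`` shifts every attribute, giving genuinely
    separated classes.
    """
    import pandas as pd

    from cardiostate.classify import FeatureTable

    rng = np.random.default_rng(seed)
    rows, states, subs = [], [], []
    names = [f"attr_{k}" for k in range(n_attrs)]
    for ci, c in enumerate(["awake", "sevoflurane", "propofol"]):
        for j in range(n_per_class):
            x = noise * rng.standard_normal(n_attrs)
            if informative == "all":
                x += ci * gap
            else:
                x[informative] += ci * gap
            rows.append(pd.Series(x, index=names))
            states.append(c)
            subs.append(f"{c[:2]}{j:02d}")
    return FeatureTable.from_rows(rows, states, subs)
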