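"""Reading and writing recordings and derived tables as delimited text.

A :class:`~cardiostate.synthetic.SignalRecord` round-trips through a
tab-separated file with two comment header lines carrying the sampling
rate and labels, one column per channel plus a leading time column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventSeries
from .synthetic import SignalRecord

__all__ = ["write_record", "read_record", "write_events", "read_events"]


def write_record(record: SignalRecord, path: str | Path) -> Path:
    """Write a multichannel record as delimited text with a metadata header."""
    path = Path(path)
    n = int(round(record.fs * record.duration))
    t = np.arange(n) / record.fs
    df = pd.DataFrame({"time": t, **record.channels})
    with open(path, "w") as fh:
        fh.write("# cardiostate signal record\n")
        fh.write(
            f"# fs={record.fs} duration={record.duration} "
            f"subject={record.subject_id or 'unknown'} state={record.state}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return path


def read_record(path: str | Path) -> SignalRecord:
    """Read a record written by :func:`write_record`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line.lstrip("# ").split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    df = pd.read_csv(path, sep="\t", comment="#")
    fs = float(meta["fs"])
    channels = {c: df[c].to_numpy() for c in df.columns if c != "time"}
    n = len(df)
    return SignalRecord(
        channels=channels,
        fs=fs,
        duration=n / fs,
        subject_id=meta.get("subject", ""),
        state=meta.get("state", "awake"),
    )


def write_events(events: EventSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time": events.times, "kind": events.kind}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
    return path


def read_events(path: str | Path) -> EventSeries:
    df = pd.read_csv(path, sep="\t")
    kind = str(df["kind"].iloc[0]) if len(df) else "unknown"
    return EventSeries(times=df["time"].to_numpy(), kind=kind)
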