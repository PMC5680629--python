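"""Readers and writers for the plain-text data dialects.

detections CSV: ``fish_id,antenna,timestamp`` with ISO-8601 timestamps and
antenna in {close_spot, distant_spot, shelter}; captures CSV:
``fish_id,day,session`` (1-based); traits CSV: ``fish_id,pond,tl_mm,growth_mm``.
"""

from __future__ import annotations

import pandas as pd

from .config import ANTENNAS

_TS_FMT = "%Y-%m-%dT%H:%M:%S"


def write_detections(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(_TS_FMT)
    out[["fish_id", "antenna", "timestamp"]].to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"fish_id": str, "antenna": str})
    missing = {"fish_id", "antenna", "timestamp"} - set(df.columns)
    if missing:
        raise ValueError(f"detections file {path} missing columns: {sorted(missing)}")
    bad = set(df["antenna"].unique()) - set(ANTENNAS)
    if bad:
        raise ValueError(f"unknown antenna labels in {path}: {sorted(bad)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    return df


def write_captures(df: pd.DataFrame, path) -> None:
    df[["fish_id", "day", "session"]].to_csv(path, index=False)


def read_captures(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"fish_id": str})
    missing = {"fish_id", "day", "session"} - set(df.columns)
    if missing:
        raise ValueError(f"captures file {path} missing columns: {sorted(missing)}")
    df["day"] = df["day"].astype(int)
    df["session"] = df["session"].astype(int)
    return df


def write_traits(df: pd.DataFrame, path) -> None:
    out = df[["fish_id", "pond", "tl_mm", "growth_mm"]].copy()
    out.to_csv(path, index=False, float_format="%.6f")


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"fish_id": str})
    missing = {"fish_id", "pond", "tl_mm", "growth_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"traits file {path} missing columns: {sorted(missing)}")
    df["pond"] = df["pond"].astype(int)
    return df
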