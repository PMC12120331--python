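"""Delimited-text readers and writers for every pipeline artifact.

All formats are plain comma-separated text with a header row:

* logger records — ``timestamp,hr_bpm,qi,temp_c,avg_ea_mg`` (ISO-8601 timestamps)
* feeding log — ``date,tf_tons``
* daily summaries — ``date,hrm,tpm,tpiq,acm,tf,n_records``
* ECG / single-channel bursts — ``time_s,value``
* tri-axial bursts — ``time_s,ax_mg,ay_mg,az_mg``
* flat key-value config files — one ``key = value`` per line, ``#`` comments
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signals import AccelBurst, ECGTrace

__all__ = [
    "write_records", "read_records",
    "write_feeding", "read_feeding",
    "write_daily", "read_daily",
    "write_ecg", "read_ecg",
    "write_accel", "read_accel",
    "write_keyvalue", "read_keyvalue",
]


def write_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False, float_format="%.6g")


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df["hr_bpm"] = df["hr_bpm"].astype(int)
    df["qi"] = df["qi"].astype(int)
    return df


def write_feeding(feeding: pd.DataFrame, path) -> None:
    feeding.to_csv(path, index=False, float_format="%.6g")


def read_feeding(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_daily(daily: pd.DataFrame, path) -> None:
    daily.to_csv(path, index=False, float_format="%.6g")


def read_daily(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["hrm"] = df["hrm"].astype(int)
    return df


def write_ecg(trace: ECGTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.samples}).to_csv(
        path, index=False, float_format="%.8g"
    )


def read_ecg(path) -> ECGTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("burst file must contain at least two samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    return ECGTrace(sample_rate=rate, samples=df["value"].to_numpy(float))


def write_accel(burst: AccelBurst, path) -> None:
    t = np.arange(len(burst)) / burst.sample_rate
    pd.DataFrame(
        {"time_s": t, "ax_mg": burst.ax, "ay_mg": burst.ay, "az_mg": burst.az}
    ).to_csv(path, index=False, float_format="%.8g")


def read_accel(path) -> AccelBurst:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("burst file must contain at least two samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    return AccelBurst(
        sample_rate=rate,
        ax=df["ax_mg"].to_numpy(float),
        ay=df["ay_mg"].to_numpy(float),
        az=df["az_mg"].to_numpy(float),
    )


def write_keyvalue(mapping: dict, path) -> None:
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_keyvalue(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
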