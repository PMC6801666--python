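"""Readers for the delimited-text study input formats."""

from __future__ import annotations

import pathlib

import pandas as pd


def read_temperature(path: str | pathlib.Path, sep: str = ",") -> pd.DataFrame:
    """Read (region_id, date, tmax_c, tmin_c) into the internal schema."""
    df = pd.read_csv(path, sep=sep)
    rename = {"tmax_c": "tmax", "tmin_c": "tmin"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    df["date"] = pd.to_datetime(df["date"])
    return df[["region_id", "date", "tmax", "tmin"]]


def read_pm25(path: str | pathlib.Path, sep: str = ",") -> pd.DataFrame:
    """Read (station_id, date, pm25); blank pm25 values become NaN."""
    df = pd.read_csv(path, sep=sep)
    df["date"] = pd.to_datetime(df["date"])
    df["pm25"] = pd.to_numeric(df["pm25"], errors="coerce")
    return df[["station_id", "date", "pm25"]]


def read_holidays(path: str | pathlib.Path) -> list:
    """Read a holiday calendar, one ISO date per line; blank lines ignored."""
    lines = pathlib.Path(path).read_text().splitlines()
    return [pd.Timestamp(line.strip()).date() for line in lines if line.strip()]
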