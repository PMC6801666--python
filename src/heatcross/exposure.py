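"""Daily exposure covariates: PM2.5 gap-filling, holiday flags, exposure table.

PM2.5 enters the regression as a daily 24-h mean per region (nearest monitor).
Monitoring series have occasional outages, handled by a two-regime rule:

* short gaps (1-2 consecutive missing days): filled with the mean of the
  neighbouring observed days -- up to 7 observed days on each side, pooled;
* longer gaps (3+ days): linear interpolation between the nearest observed
  values on either side.

The short-gap rule can alternatively average the two one-sided means
(``short_gap_rule="two_means"``); the pooled reading is the default.  Filled
values are floored at zero (concentrations are non-negative) and flagged.
"""

from __future__ import annotations

import datetime as dt
from collections.abc import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "fill_pm25_gaps",
    "holiday_flags",
    "map_stations_to_regions",
    "assemble_exposure_table",
]


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive True values."""
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fill_pm25_gaps(
    series: pd.DataFrame,
    *,
    short_gap_rule: str = "pooled",
    max_short_gap: int = 2,
    neighbor_days: int = 7,
) -> pd.DataFrame:
    """Fill missing values in a daily PM2.5 series.

    Parameters
    ----------
    series : DataFrame
        Columns (station_id, date, pm25) with consecutive dates per station
        and NaN for missing days.
    short_gap_rule : {"pooled", "two_means"}
        How the neighbourhood mean for short gaps is formed: "pooled" takes
        one mean over up to ``neighbor_days`` observed days on each side
        pooled together; "two_means" averages the before-mean and after-mean.
    max_short_gap : int
        Longest gap (days) filled with the neighbourhood rule; longer gaps
        are linearly interpolated between the nearest observed anchors.

    Returns the frame with no missing pm25 and a ``pm25_filled`` boolean
    column marking exactly the originally missing dates.

    Raises
    ------
    ValueError
        For a gap touching the series boundary ("unbounded gap": no observed
        anchor on one side), or non-consecutive dates.
    """
    if short_gap_rule not in ("pooled", "two_means"):
        raise ValueError(f"unknown short_gap_rule {short_gap_rule!r}")
    out = series.copy()
    out["date"] = pd.to_datetime(out["date"])
    out = out.sort_values(["station_id", "date"]).reset_index(drop=True)
    out["pm25"] = out["pm25"].astype(float)
    out["pm25_filled"] = out["pm25"].isna()
    for station, grp in out.groupby("station_id", sort=False):
        gaps = grp["date"].diff().dropna()
        if (gaps != pd.Timedelta(days=1)).any():
            raise ValueError(f"dates not consecutive for station {station!r}")
        values = grp["pm25"].to_numpy(copy=True)
        observed = ~np.isnan(values)
        for start, stop in _missing_runs(np.isnan(values)):
            if start == 0 or stop == len(values):
                when = grp["date"].iloc[start].date()
                raise ValueError(
                    f"unbounded gap at series boundary for station {station!r} "
                    f"starting {when}"
                )
            length = stop - start
            if length <= max_short_gap:
                before = values[:start][observed[:start]][-neighbor_days:]
                after = values[stop:][observed[stop:]][:neighbor_days]
                if before.size == 0 or after.size == 0:
                    fill = _linear_fill(values, start, stop)
                elif short_gap_rule == "pooled":
                    fill = float(np.concatenate([before, after]).mean())
                else:
                    fill = (before.mean() + after.mean()) / 2.0
                values[start:stop] = fill
            else:
                values[start:stop] = _linear_fill(values, start, stop)
        out.loc[grp.index, "pm25"] = np.maximum(values, 0.0)
    return out


def _linear_fill(values: np.ndarray, start: int, stop: int) -> np.ndarray:
    """Linear interpolation across values[start:stop] between its anchors."""
    left, right = values[start - 1], values[stop]
    k = np.arange(1, stop - start + 1)
    return left + (right - left) * k / (stop - start + 1)


def holiday_flags(
    dates: Iterable[dt.date | str | pd.Timestamp],
    holidays: Iterable[dt.date | str | pd.Timestamp],
) -> np.ndarray:
    """Boolean flag per date: is the date a public holiday?"""
    hol = {pd.Timestamp(h).normalize() for h in holidays}
    return np.array([pd.Timestamp(d).normalize() in hol for d in dates], dtype=bool)


def map_stations_to_regions(
    pm25: pd.DataFrame, station_to_region: dict[str, str]
) -> pd.DataFrame:
    """Relabel a station-keyed PM2.5 frame by the region each monitor serves.

    The default study mapping is New Town -> Hobart, Ti Tree Bend ->
    Launceston; the mapping is configuration, not code.
    """
    unknown = set(pm25["station_id"]) - set(station_to_region)
    if unknown:
        raise ValueError(f"no region mapping for stations: {sorted(unknown)}")
    out = pm25.copy()
    out["region_id"] = out["station_id"].map(station_to_region)
    return out


def assemble_exposure_table(
    calendar: pd.DataFrame,
    pm25: pd.DataFrame,
    holidays: Iterable[dt.date | str | pd.Timestamp],
    study_start: dt.date | str,
    study_end: dt.date | str,
) -> pd.DataFrame:
    """Per-region-day covariate table for the study window.

    Joins the heatwave calendar (``exposed``), gap-filled PM2.5 (keyed by
    region_id) and the holiday flag over every day in
    ``[study_start, study_end]``.  Each region must cover the full window in
    both inputs.

    Returns columns (region_id, date, exposed, pm25, holiday, pm25_filled).
    """
    start, end = pd.Timestamp(study_start), pd.Timestamp(study_end)
    window = pd.date_range(start, end, freq="D")
    if "region_id" not in pm25.columns:
        raise ValueError("pm25 frame must carry region_id (map_stations_to_regions)")
    if pm25["pm25"].isna().any():
        raise ValueError("pm25 has missing values; run fill_pm25_gaps first")
    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"])
    pm = pm25.copy()
    pm["date"] = pd.to_datetime(pm["date"])
    frames = []
    for region in cal["region_id"].unique():
        c = cal[cal["region_id"] == region].set_index("date")
        p = pm[pm["region_id"] == region].set_index("date")
        for name, df in (("calendar", c), ("pm25", p)):
            missing = window.difference(df.index)
            if len(missing):
                dates = ", ".join(str(d.date()) for d in missing[:5])
                raise ValueError(
                    f"{name} for region {region!r} missing {len(missing)} "
                    f"study days (first: {dates})"
                )
        df = pd.DataFrame(
            {
                "region_id": region,
                "date": window,
                "exposed": c.loc[window, "exposed"].to_numpy(),
                "pm25": p.loc[window, "pm25"].to_numpy(),
                "holiday": holiday_flags(window, holidays),
                "pm25_filled": p.loc[window, "pm25_filled"].to_numpy()
                if "pm25_filled" in p.columns
                else False,
            }
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
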